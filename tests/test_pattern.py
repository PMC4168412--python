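import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_rate_pm, brute_force_train
from ecgpm import SynthConfig, generate
from ecgpm.io import ECGRecord
from ecgpm.pattern import (
    PatternMatrix,
    PatternMatrixClassifier,
    WindowSpec,
    classify_beat,
    compute_rate_pm,
    extract_pqrst,
    quantize_beat,
    train_from_record,
    train_matrix,
)


class TestWindowSpec:
    def test_geometry_at_360hz(self):
        spec = WindowSpec(fs=360)
        assert (spec.n_pre, spec.n_post, spec.n_total) == (80, 137, 218)

    def test_geometry_at_250hz(self):
        spec = WindowSpec(fs=250)
        assert (spec.n_pre, spec.n_post, spec.n_total) == (55, 95, 151)

    def test_extract_length_and_bounds(self, clean_record):
        spec = WindowSpec(fs=clean_record.fs)
        r = clean_record.annotations[3].sample_index
        assert len(extract_pqrst(clean_record, r, spec)) == 218
        assert extract_pqrst(clean_record, 50, spec) is None  # needs 80 before


class TestQuantize:
    def test_constant_window_maps_to_middle_row(self):
        q = quantize_beat(np.full(218, 512.0), 81)
        assert np.all(q.rows == 40)

    def test_endpoints_and_midpoint(self):
        q = quantize_beat(np.array([0.0, 511.5, 1023.0]), 81)
        assert list(q.rows) == [0, 40, 80]

    @given(st.lists(st.floats(0, 1023), min_size=2, max_size=50), st.integers(2, 128))
    @settings(max_examples=50, deadline=None)
    def test_extremes_hit_first_and_last_rows(self, xs, a_rows):
        x = np.array(xs)
        q = quantize_beat(x, a_rows)
        assert q.rows.min() >= 0 and q.rows.max() <= a_rows - 1
        if x.max() > x.min():
            assert q.rows[np.argmin(x)] == 0
            assert q.rows[np.argmax(x)] == a_rows - 1


class TestTraining:
    def test_single_beat_leaves_triplet_columns(self):
        rows = np.array([0, 5, 40, 80])
        m = train_matrix([quantize_beat_rows(rows, 81)], 81)
        for i, r in enumerate(rows):
            col = m.cells[i]
            expect = {rr for rr in (r - 1, r, r + 1) if 0 <= rr <= 80}
            assert set(np.nonzero(col)[0]) == expect
            assert np.all(col[sorted(expect)] == 1)

    def test_twelve_identical_beats_saturate_at_cap(self):
        rows = np.array([10, 20, 30])
        m = train_matrix([quantize_beat_rows(rows, 81)] * 12, 81)
        assert np.all(m.cells[np.arange(3), rows] == 10)
        assert m.cells.max() == 10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        beats_rows = [rng.integers(0, 9, size=20) for _ in range(50)]
        m = train_matrix([quantize_beat_rows(r, 9) for r in beats_rows], 9)
        oracle = brute_force_train(beats_rows, 9)
        assert np.array_equal(m.cells, oracle)
        probe = rng.integers(0, 9, size=20)
        got = compute_rate_pm(m, quantize_beat_rows(probe, 9))
        assert got == brute_force_rate_pm(oracle, probe)

    def test_monotone_in_training_beats(self):
        rng = np.random.default_rng(0)
        beats = [quantize_beat_rows(rng.integers(0, 81, 218), 81) for _ in range(8)]
        probe = quantize_beat_rows(rng.integers(0, 81, 218), 81)
        prev_cells = np.zeros((218, 81))
        prev_rate = 0
        for k in range(1, 9):
            m = train_matrix(beats[:k], 81)
            assert np.all(m.cells >= prev_cells)
            rate = compute_rate_pm(m, probe)
            assert rate >= prev_rate
            prev_cells, prev_rate = m.cells, rate

    def test_order_independent_below_saturation(self):
        rng = np.random.default_rng(3)
        beats = [quantize_beat_rows(rng.integers(0, 81, 30), 81) for _ in range(6)]
        a = train_matrix(beats, 81)
        b = train_matrix(beats[::-1], 81)
        assert np.array_equal(a.cells, b.cells)

    def test_errors(self):
        with pytest.raises(ValueError):
            train_matrix([], 81)
        with pytest.raises(ValueError):
            train_matrix(
                [quantize_beat_rows(np.zeros(5, int), 81),
                 quantize_beat_rows(np.zeros(6, int), 81)],
                81,
            )


class TestRatePM:
    def test_self_match_after_saturation_is_full_length(self, one_window):
        q = quantize_beat(one_window, 81)
        m = train_matrix([q] * 10, 81)
        assert compute_rate_pm(m, q) == 218

    def test_untrained_matrix_scores_zero(self, one_window):
        q = quantize_beat(one_window, 81)
        empty = PatternMatrix(
            cells=np.zeros((218, 81), np.uint8), a_rows=81,
            trained_beats=0, template=np.zeros(218),
        )
        assert compute_rate_pm(empty, q) == 0

    def test_two_row_shift_escapes_the_one_row_smear(self):
        rows = np.full(218, 40)
        m = train_matrix([quantize_beat_rows(rows, 81)] * 10, 81)
        shifted = quantize_beat_rows(rows + 2, 81)
        assert compute_rate_pm(m, shifted) == 0
        assert compute_rate_pm(m, shifted) == brute_force_rate_pm(
            brute_force_train([rows] * 10, 81), rows + 2
        )

    def test_length_mismatch_rejected(self, one_window):
        m = train_matrix([quantize_beat(one_window, 81)], 81)
        with pytest.raises(ValueError):
            compute_rate_pm(m, quantize_beat_rows(np.zeros(10, int), 81))


class TestClassify:
    @pytest.mark.parametrize(
        "rate, expected", [(218, "N"), (102, "A"), (180, "A"), (181, "N")]
    )
    def test_threshold_rule(self, rate, expected):
        assert classify_beat(rate, 180) == expected


class TestTrainFromRecord:
    def test_clean_training_yields_enough_beats(self, clean_record):
        m = train_from_record(clean_record, 30.0)
        assert m.trained_beats >= 30

    def test_training_beats_score_high_against_their_own_matrix(self, clean_record):
        from ecgpm.rpeak import detect_rpeaks, lowpass_filter

        m = train_from_record(clean_record, 30.0)
        spec = WindowSpec(fs=clean_record.fs)
        head = ECGRecord(
            samples=clean_record.samples[: int(30 * clean_record.fs)],
            fs=clean_record.fs,
        )
        filtered = lowpass_filter(head, 35.0)
        for r in detect_rpeaks(head).peaks:
            w = extract_pqrst(filtered, int(r), spec)
            if w is None:
                continue
            assert compute_rate_pm(m, quantize_beat(w, 81)) >= 200

    def test_short_record_is_a_training_error(self):
        rec = generate(SynthConfig(duration_s=10, seed=5))
        with pytest.raises(ValueError):
            train_from_record(rec, 30.0)


class TestSerialization:
    def test_blob_round_trip(self, one_window):
        m = train_matrix([quantize_beat(one_window, 81)] * 3, 81)
        back = PatternMatrix.from_bytes(m.to_bytes())
        assert np.array_equal(back.cells, m.cells)
        assert back.trained_beats == 3
        assert np.allclose(back.template, m.template, atol=1e-4)

    def test_bad_magic_rejected(self):
        with pytest.raises(ValueError):
            PatternMatrix.from_bytes(b"NOPE" + b"\0" * 20)


class TestEstimator:
    def test_fit_predict_separates_morphologies(self, clean_record):
        spec = WindowSpec(fs=clean_record.fs)
        wins = [
            extract_pqrst(clean_record, a.sample_index, spec)
            for a in clean_record.annotations
        ]
        wins = np.array([w for w in wins if w is not None])
        clf = PatternMatrixClassifier().fit(wins[:30])
        assert set(clf.predict(wins[30:])) == {"N"}
        assert np.all(clf.decision_function(wins[30:]) > 180)
        # a structurally different beat (inverted) must read abnormal
        assert clf.predict((wins[0].max() - wins[:1]))[0] == "A"

    def test_sklearn_params_contract(self):
        clf = PatternMatrixClassifier(a_rows=33, threshold=25)
        assert clf.get_params() == {"a_rows": 33, "threshold": 25}
        clf.set_params(threshold=180)
        assert clf.threshold == 180


def quantize_beat_rows(rows, a_rows):
    """Build a QuantizedBeat directly from a row trajectory."""
    from ecgpm.pattern import QuantizedBeat

    rows = np.asarray(rows, dtype=int)
    return QuantizedBeat(rows=rows, r_index=0, raw_window=rows.astype(float))
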