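import numpy as np
import pytest

from ecgpm import SynthConfig, generate


@pytest.fixture(scope="session")
def clean_record():
    """60 s of noise-free normal rhythm at 72 bpm, 360 Hz."""
    return generate(SynthConfig(duration_s=60, mean_hr_bpm=72, abnormal_rate=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_record():
    """120 s with 10% abnormal beats and 20 dB white noise."""
    return generate(
        SynthConfig(duration_s=120, abnormal_rate=0.1, white_snr_db=20.0, seed=2)
    )


@pytest.fixture(scope="session")
def one_window(clean_record):
    """One in-bounds PQRST window (length 218) from the clean record."""
    from ecgpm.pattern import WindowSpec, extract_pqrst

    spec = WindowSpec(fs=clean_record.fs)
    for a in clean_record.annotations:
        w = extract_pqrst(clean_record, a.sample_index, spec)
        if w is not None:
            return w
    raise RuntimeError("no in-bounds beat in fixture record")


def brute_force_train(rows_list, a_rows, cap=10):
    """Literal cell-by-cell reimplementation of the training increments."""
    n = len(rows_list[0])
    cells = [[0] * a_rows for _ in range(n)]
    for rows in rows_list:
        for i in range(n):
            for r in (rows[i], rows[i] - 1, rows[i] + 1):
                if 0 <= r < a_rows and cells[i][r] < cap:
                    cells[i][r] += 1
    return np.array(cells)


def brute_force_rate_pm(cells, rows):
    return sum(1 for i, r in enumerate(rows) if cells[i][r] > 7)
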