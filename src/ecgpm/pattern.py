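"""Heartbeat template matching against a trained occupancy matrix.

A heartbeat is represented by a fixed window around its R peak: 220 ms
before to 380 ms after, which at 360 Hz gives 80 + 1 + 137 = 218 samples.
Each window is min-max quantized to ``A`` amplitude rows (default 81), so
a beat becomes a trajectory through a ``n_total x A`` grid.

Training accumulates trajectories of normal beats into the grid: for each
column the visited cell and its two vertical neighbours are incremented,
each saturating at 10.  The +/-1 smear builds amplitude tolerance into the
template so minor beat-to-beat variation still matches.

Matching counts the columns of an incoming beat whose cell holds a count
greater than 7 — the ``ratePM`` statistic, at most ``n_total`` (218).  A
beat with ratePM above the classification threshold (default 180) is
normal (``'N'``); anything at or below is abnormal (``'A'``).

The estimator :class:`PatternMatrixClassifier` wraps train/match/classify
in the scikit-learn fit/predict idiom; the module-level functions are thin
wrappers kept for pipeline-style use.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import ECGRecord
from .rpeak import RPeakParams, detect_rpeaks

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "QuantizedBeat",
    "PatternMatrix",
    "PatternMatrixClassifier",
    "extract_pqrst",
    "quantize_beat",
    "train_matrix",
    "compute_rate_pm",
    "classify_beat",
    "train_from_record",
]

CELL_CAP = 10          # per-cell saturation during training
MATCH_MIN_EXCLUSIVE = 7  # a cell counts toward ratePM iff its value > 7
DEFAULT_THRESHOLD = 180  # ratePM > threshold -> normal
DEFAULT_A = 81


@dataclass(frozen=True)
class WindowSpec:
    """PQRST window geometry: 220 ms before the R peak to 380 ms after."""

    fs: float
    pre_ms: float = 220.0
    post_ms: float = 380.0

    @property
    def n_pre(self) -> int:
        return int(np.ceil(self.pre_ms * self.fs / 1000))

    @property
    def n_post(self) -> int:
        return int(np.ceil(self.post_ms * self.fs / 1000))

    @property
    def n_total(self) -> int:
        return self.n_pre + 1 + self.n_post


@dataclass
class QuantizedBeat:
    """One beat as an amplitude-row trajectory plus its raw window."""

    rows: np.ndarray          # (n_total,) ints in [0, A-1]
    r_index: int              # R-peak sample index in the source record
    raw_window: np.ndarray    # (n_total,) raw samples


@dataclass
class PatternMatrix:
    """The trained time x amplitude occupancy grid plus the mean template."""

    cells: np.ndarray         # (n_total, A) uint8, each in [0, CELL_CAP]
    a_rows: int
    trained_beats: int
    template: np.ndarray      # (n_total,) mean of raw training windows
    classify_threshold: int = DEFAULT_THRESHOLD

    @property
    def n_total(self) -> int:
        return self.cells.shape[0]

    def to_bytes(self) -> bytes:
        """Versioned binary blob: magic 'PMX1', dims, cells, template."""
        head = b"PMX1" + struct.pack(
            "<HHH", self.n_total, self.a_rows, self.trained_beats
        )
        return (
            head
            + self.cells.astype(np.uint8).tobytes()
            + self.template.astype("<f4").tobytes()
        )

    @classmethod
    def from_bytes(cls, blob: bytes) -> "PatternMatrix":
        if blob[:4] != b"PMX1":
            raise ValueError("not a PMX1 pattern-matrix blob")
        n_total, a_rows, trained = struct.unpack("<HHH", blob[4:10])
        off = 10
        cells = np.frombuffer(
            blob[off : off + n_total * a_rows], dtype=np.uint8
        ).reshape(n_total, a_rows).copy()
        off += n_total * a_rows
        template = np.frombuffer(blob[off : off + 4 * n_total], dtype="<f4").astype(float)
        return cls(cells=cells, a_rows=a_rows, trained_beats=trained, template=template)


def extract_pqrst(record: ECGRecord, r_index: int, spec: WindowSpec) -> np.ndarray | None:
    """Slice the PQRST window around ``r_index``; None if out of bounds.

    Out-of-bounds beats are dropped (with a logged warning) rather than
    raising, matching streaming use where edge beats are simply skipped.
    """
    lo = r_index - spec.n_pre
    hi = r_index + spec.n_post
    if lo < 0 or hi >= len(record.samples):
        logger.warning("beat at %d dropped: PQRST window out of bounds", r_index)
        return None
    return record.samples[lo : hi + 1].copy()


def quantize_beat(raw_window: np.ndarray, a_rows: int = DEFAULT_A, r_index: int = 0) -> QuantizedBeat:
    """Min-max quantize one window to ``a_rows`` amplitude levels.

    ``rows[i] = round((x[i] - min) / (max - min) * (A - 1))``; a constant
    window maps to the middle row.
    """
    x = np.asarray(raw_window, dtype=float)
    if x.ndim != 1:
        raise ValueError("raw_window must be 1-D")
    lo, hi = x.min(), x.max()
    if hi == lo:
        rows = np.full(len(x), a_rows // 2, dtype=int)
    else:
        rows = np.rint((x - lo) / (hi - lo) * (a_rows - 1)).astype(int)
    return QuantizedBeat(rows=rows, r_index=r_index, raw_window=x)


def train_matrix(beats: list[QuantizedBeat], a_rows: int = DEFAULT_A) -> PatternMatrix:
    """Accumulate beat trajectories into a fresh occupancy matrix.

    For each beat and column ``i`` the cells ``(i, row)``, ``(i, row-1)``
    and ``(i, row+1)`` are each incremented if currently below the cap of
    10; neighbour increments outside ``[0, A-1]`` are skipped.
    """
    if not beats:
        raise ValueError("need at least one training beat")
    n_total = len(beats[0].rows)
    if any(len(b.rows) != n_total for b in beats):
        raise ValueError("training beats have mixed window lengths")
    cells = np.zeros((n_total, a_rows), dtype=np.uint8)
    cols = np.arange(n_total)
    for b in beats:
        for offset in (0, -1, 1):
            r = b.rows + offset
            ok = (r >= 0) & (r < a_rows)
            c, r = cols[ok], r[ok]
            inc = cells[c, r] < CELL_CAP
            cells[c[inc], r[inc]] += 1
    template = np.mean([b.raw_window for b in beats], axis=0)
    return PatternMatrix(
        cells=cells, a_rows=a_rows, trained_beats=len(beats), template=template
    )


def compute_rate_pm(matrix: PatternMatrix, beat: QuantizedBeat) -> int:
    """Count columns whose visited cell is well supported (count > 7)."""
    if len(beat.rows) != matrix.n_total:
        raise ValueError(
            f"beat length {len(beat.rows)} != matrix n_total {matrix.n_total}"
        )
    hits = matrix.cells[np.arange(matrix.n_total), beat.rows] > MATCH_MIN_EXCLUSIVE
    return int(hits.sum())


def classify_beat(rate_pm: int, threshold: int = DEFAULT_THRESHOLD) -> str:
    """'N' if ratePM is strictly above the threshold, else 'A'."""
    return "N" if rate_pm > threshold else "A"


class PatternMatrixClassifier(ClassifierMixin, BaseEstimator):
    """Normal/abnormal heartbeat classifier by occupancy-matrix matching.

    Fit on raw PQRST windows of *normal* beats (rows of ``X``); prediction
    quantizes each incoming window, computes its ratePM against the
    trained matrix and labels it ``'N'`` (ratePM > ``threshold``) or
    ``'A'``.

    Parameters
    ----------
    a_rows : int
        Number of amplitude quantization rows (matrix width).
    threshold : int
        Classification threshold on ratePM.  The default 180 suits a
        218-sample window; an evaluation-mode preset of 35 is also in use
        for annotated-database screening.

    Attributes
    ----------
    matrix_ : PatternMatrix
        The trained occupancy grid, cell counts in [0, 10].
    n_features_in_ : int
        Window length (218 at 360 Hz with the default window).
    """

    def __init__(self, a_rows: int = DEFAULT_A, threshold: int = DEFAULT_THRESHOLD):
        self.a_rows = a_rows
        self.threshold = threshold

    def fit(self, X, y=None) -> "PatternMatrixClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be (n_beats, window_len) with n_beats >= 1")
        beats = [quantize_beat(row, self.a_rows) for row in X]
        self.matrix_ = train_matrix(beats, self.a_rows)
        self.matrix_.classify_threshold = self.threshold
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array(["A", "N"])
        return self

    def decision_function(self, X) -> np.ndarray:
        """ratePM of each window against the trained matrix."""
        check_is_fitted(self, "matrix_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array(
            [compute_rate_pm(self.matrix_, quantize_beat(row, self.a_rows)) for row in X]
        )

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > self.threshold, "N", "A")


def train_from_record(
    record: ECGRecord,
    train_seconds: float = 30.0,
    params: RPeakParams | None = None,
    spec: WindowSpec | None = None,
    a_rows: int = DEFAULT_A,
) -> PatternMatrix:
    """Detect beats in the first ``train_seconds`` and train the matrix.

    Every in-bounds PQRST window found in the training span contributes;
    fewer than two usable beats is a training error.
    """
    if record.duration_s < train_seconds:
        raise ValueError(
            f"record ({record.duration_s:.1f} s) shorter than the "
            f"{train_seconds:.0f} s training span"
        )
    spec = spec or WindowSpec(fs=record.fs)
    n_train = int(round(train_seconds * record.fs))
    head = ECGRecord(
        samples=record.samples[:n_train], fs=record.fs,
        units=record.units, adc_bits=record.adc_bits,
    )
    result = detect_rpeaks(head, params)
    # match on the band-limited signal: quantized trajectories come from the
    # low-pass-filtered ECG so wideband noise does not erode the match,
    # while the raw windows still feed the template
    from .rpeak import lowpass_filter

    cutoff = (params or RPeakParams()).lp_cutoff
    filtered = lowpass_filter(head, cutoff)
    beats = []
    for r in result.peaks:
        w_raw = extract_pqrst(head, int(r), spec)
        w_flt = extract_pqrst(filtered, int(r), spec)
        if w_raw is not None and w_flt is not None:
            b = quantize_beat(w_flt, a_rows, r_index=int(r))
            b.raw_window = w_raw
            beats.append(b)
    if len(beats) < 2:
        raise ValueError(
            f"only {len(beats)} usable beats in the {train_seconds:.0f} s "
            "training span; cannot train"
        )
    return train_matrix(beats, a_rows)
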