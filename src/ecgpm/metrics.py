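"""Evaluation metrics for the telemetry pipeline.

Compression ratio is raw bytes over transmitted bytes.  Signal fidelity
(Pearson correlation and RMSE) is computed after min-max normalizing both
signals to [0, 1] over the compared span, so RMSE lands on a 0–1 scale.
Detection accuracies pair detected beats with reference annotations by a
greedy one-to-one match within a time tolerance (default 50 ms); the
abnormal-detection accuracy is true positives over the number of
reference-abnormal beats, with false alarms reported separately (so an
over-detecting run can still score below 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import BeatAnnotation, ECGRecord
from .reconstruct import ReconstructedSignal

__all__ = [
    "EvalReport",
    "compression_ratio",
    "correlation_and_rmse",
    "match_beats",
    "rpeak_accuracy",
    "abnormal_accuracy",
]


@dataclass
class EvalReport:
    """Per-record summary mirroring the usual CR / CC / RMSE / accuracy table."""

    cr: float
    cc: float
    rmse: float
    rpeak_accuracy_pct: float
    abnormal_accuracy_pct: float | None
    total_beats: int
    detected_peaks: int
    abnormal_true: int
    abnormal_detected: int
    false_alarms: int
    raw_bytes: int
    tx_bytes: int

    def to_dict(self) -> dict:
        return asdict(self)


def compression_ratio(raw_bytes: int, tx_bytes: int) -> float:
    """Raw over transmitted byte count; exact quotient."""
    if tx_bytes <= 0:
        raise ValueError("tx_bytes must be positive")
    return raw_bytes / tx_bytes


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("zero-variance signal: correlation undefined")
    return (x - lo) / (hi - lo)


def correlation_and_rmse(
    original: ECGRecord | np.ndarray,
    recon: ReconstructedSignal | np.ndarray,
) -> tuple[float, float]:
    """Pearson r and RMS difference on the overlap, both signals min-max
    normalized to [0, 1] first."""
    a = original.samples if hasattr(original, "samples") else np.asarray(original, float)
    b = recon.samples if hasattr(recon, "samples") else np.asarray(recon, float)
    n = min(len(a), len(b))
    if n < 2:
        raise ValueError("need an overlap of at least 2 samples")
    a, b = _minmax(np.asarray(a[:n], float)), _minmax(np.asarray(b[:n], float))
    cc = float(np.corrcoef(a, b)[0, 1])
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return cc, rmse


def match_beats(
    detected: np.ndarray, reference: np.ndarray, fs: float, tol_ms: float = 50.0
) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing of detected and reference indices.

    Reference beats are taken in order; each grabs the nearest unused
    detection within ``tol_ms``.  Returns (reference_pos, detected_pos)
    index pairs into the two arrays.
    """
    tol = tol_ms * fs / 1000.0
    detected = np.asarray(detected, dtype=float)
    used = np.zeros(len(detected), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, r in enumerate(np.asarray(reference)):
        if len(detected) == 0:
            break
        d = np.abs(detected - r)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            pairs.append((i, j))
    return pairs


def rpeak_accuracy(
    detected: np.ndarray, reference: np.ndarray, fs: float, tol_ms: float = 50.0
) -> float:
    """Percentage of reference beats matched by a detection within tol_ms."""
    reference = np.asarray(reference)
    if len(reference) == 0:
        raise ValueError("reference beat list is empty")
    pairs = match_beats(detected, reference, fs, tol_ms)
    return 100.0 * len(pairs) / len(reference)


def abnormal_accuracy(
    beat_log: list[tuple[str, int, int]],
    reference: list[BeatAnnotation],
    fs: float,
    tol_ms: float = 50.0,
) -> tuple[float | None, int, int, int]:
    """Abnormal-beat detection accuracy against reference annotations.

    Returns ``(accuracy_pct, n_reference_abnormal, n_flagged_correct,
    false_alarms)``; accuracy is None when the reference contains no
    abnormal beats (metric not applicable).
    """
    det_pos = np.array([pos for _, pos, _ in beat_log])
    det_kind = [kind for kind, _, _ in beat_log]
    ref_pos = np.array([a.sample_index for a in reference])
    pairs = match_beats(det_pos, ref_pos, fs, tol_ms)
    paired_kind = {i: det_kind[j] for i, j in pairs}

    n_abn = sum(1 for a in reference if a.label == "abnormal")
    tp = sum(
        1
        for i, a in enumerate(reference)
        if a.label == "abnormal" and paired_kind.get(i) == "A"
    )
    fa = sum(
        1
        for i, a in enumerate(reference)
        if a.label == "normal" and paired_kind.get(i) == "A"
    )
    if n_abn == 0:
        return None, 0, tp, fa
    return 100.0 * tp / n_abn, n_abn, tp, fa
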