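"""R-peak detection for single-lead ECG.

The detection chain is deliberately simple enough to run on a small
microcontroller: a 35 Hz low-pass filter removes high-frequency noise, a
short moving average suppresses mains interference, a first difference
enhances the steep QRS upstroke, and the squared difference — integrated
over a QRS-scale window so wide ventricular complexes weigh as much as
narrow ones — is compared against a variable (trailing-window)
threshold.  Accepted candidates are
refined to the apex of the low-pass-filtered ECG so that RR intervals are
measured between true R peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.ndimage import maximum_filter1d

from .io import ECGRecord

__all__ = [
    "RPeakParams",
    "RPeakResult",
    "lowpass_filter",
    "moving_average",
    "first_derivative",
    "detect_rpeaks",
    "classify_rhythm",
]


@dataclass(frozen=True)
class RPeakParams:
    """Tunable parameters of the detection chain.

    lp_cutoff : low-pass corner frequency, Hz.
    ma_width : moving-average width in samples; ``None`` means
        ``round(fs/60)``, which places a boxcar spectral null on 60 Hz
        mains (use ``round(fs/50)`` in 50 Hz regions).
    refractory_ms : minimum spacing between accepted peaks.
    thr_fraction : detection threshold as a fraction of the running
        maximum of the integrated QRS energy over the trailing
        ``thr_window_s``.
    energy_ms : width of the boxcar that integrates the squared
        derivative into QRS energy.
    """

    lp_cutoff: float = 35.0
    ma_width: int | None = None
    refractory_ms: float = 200.0
    thr_fraction: float = 0.5
    thr_window_s: float = 2.0
    refine_ms: float = 50.0
    energy_ms: float = 150.0

    def __post_init__(self) -> None:
        if self.lp_cutoff <= 0 or self.refractory_ms <= 0 or self.thr_window_s <= 0:
            raise ValueError("RPeakParams values must be positive")
        if not 0 < self.thr_fraction < 1:
            raise ValueError("thr_fraction must lie in (0, 1)")


@dataclass
class RPeakResult:
    """Detected R-peak indices plus per-beat RR intervals in ms.

    ``pre_rr_ms[0]`` is NaN (the first beat has no predecessor);
    ``pre_rr_ms[i] = (peaks[i] - peaks[i-1]) * 1000 / fs`` for i >= 1.
    """

    peaks: np.ndarray
    pre_rr_ms: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.peaks)


def lowpass_filter(record: ECGRecord, cutoff: float = 35.0, order: int = 4) -> ECGRecord:
    """Zero-phase Butterworth low-pass; unit DC gain, no peak shift."""
    if cutoff >= record.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({record.fs / 2} Hz)")
    b, a = butter(order, cutoff, btype="low", fs=record.fs)
    y = filtfilt(b, a, record.samples)
    return ECGRecord(samples=y, fs=record.fs, units="mV")


def moving_average(record: ECGRecord, width: int) -> ECGRecord:
    """Causal boxcar mean over the trailing ``width`` samples.

    Edge samples average over the available prefix, keeping the output the
    same length as the input.
    """
    if width < 1:
        raise ValueError(f"moving-average width must be >= 1, got {width}")
    x = record.samples
    if width > len(x):
        raise ValueError("moving-average width exceeds signal length")
    if width == 1:
        return ECGRecord(samples=x.copy(), fs=record.fs, units="mV")
    # direct convolution avoids the cancellation error of a cumsum approach
    sums = np.convolve(x, np.ones(width))[: len(x)]
    n = np.minimum(np.arange(1, len(x) + 1), width)
    return ECGRecord(samples=sums / n, fs=record.fs, units="mV")


def first_derivative(record: ECGRecord) -> np.ndarray:
    """First difference y[n] = x[n] - x[n-1], with y[0] = 0."""
    x = record.samples
    if len(x) < 2:
        raise ValueError("need at least 2 samples for a first derivative")
    y = np.empty_like(x)
    y[0] = 0.0
    y[1:] = np.diff(x)
    return y


def detect_rpeaks(record: ECGRecord, params: RPeakParams | None = None) -> RPeakResult:
    """Run the full detection chain on ``record``.

    Pipeline: low-pass -> causal moving average -> first difference ->
    square -> QRS-scale energy integration (``energy_ms`` boxcar).  A
    candidate is a local maximum of the energy exceeding ``thr_fraction``
    times the running maximum over the trailing ``thr_window_s`` seconds;
    candidates inside the refractory period of a stronger candidate are
    suppressed; survivors are refined to the apex of the low-pass-filtered
    ECG within ``+/- refine_ms``.
    """
    params = params or RPeakParams()
    fs = record.fs
    if len(record) < params.thr_window_s * fs:
        raise ValueError(
            f"record ({len(record) / fs:.2f} s) shorter than the threshold "
            f"window ({params.thr_window_s} s)"
        )
    lp = lowpass_filter(record, params.lp_cutoff)
    width = params.ma_width if params.ma_width is not None else max(1, round(fs / 60))
    sm = moving_average(lp, width)
    d2 = first_derivative(sm) ** 2
    # integrate the squared derivative over a QRS-scale window so that wide,
    # low-slope (ventricular) complexes carry as much weight as narrow ones
    e_win = max(1, int(round(params.energy_ms * fs / 1000)))
    energy = np.convolve(d2, np.ones(e_win), mode="same")

    win = max(1, int(round(params.thr_window_s * fs)))
    # trailing (causal) running maximum of the QRS energy
    run_max = maximum_filter1d(energy, size=win, mode="nearest", origin=(win - 1) // 2)
    thr = params.thr_fraction * run_max

    refractory = int(round(params.refractory_ms * fs / 1000))
    cand, _ = find_peaks(energy, distance=max(1, refractory))
    # absolute floor: numerical residue on near-constant signals must not
    # register as QRS energy
    floor = (1e-7 * np.abs(sm.samples).max()) ** 2 * e_win
    cand = cand[(energy[cand] > thr[cand]) & (energy[cand] > floor)]

    # refractory suppression, stronger candidate wins
    accepted: list[int] = []
    for c in cand:
        if accepted and c - accepted[-1] < refractory:
            if energy[c] > energy[accepted[-1]]:
                accepted[-1] = c
        else:
            accepted.append(c)

    # refine each detection to the apex of the filtered ECG
    half = int(round(params.refine_ms * fs / 1000))
    refined: list[int] = []
    for c in accepted:
        lo, hi = max(0, c - half), min(len(lp.samples), c + half + 1)
        r = lo + int(np.argmax(lp.samples[lo:hi]))
        if refined and r - refined[-1] < refractory:
            if lp.samples[r] > lp.samples[refined[-1]]:
                refined[-1] = r
            continue
        refined.append(r)

    peaks = np.asarray(refined, dtype=int)
    pre_rr = np.full(len(peaks), np.nan)
    if len(peaks) > 1:
        pre_rr[1:] = np.diff(peaks) * 1000.0 / fs
    return RPeakResult(peaks=peaks, pre_rr_ms=pre_rr, fs=fs)


def classify_rhythm(
    pre_rr_ms: float, brady_bpm: float = 60.0, tachy_bpm: float = 100.0
) -> str:
    """Rate-only rhythm label from one RR interval.

    HR above ``tachy_bpm`` -> ``'tachycardia'``; below ``brady_bpm`` ->
    ``'bradycardia'``; otherwise ``'normal_rate'`` (bounds inclusive on the
    normal side).
    """
    if not pre_rr_ms > 0:
        raise ValueError(f"pre_rr_ms must be positive, got {pre_rr_ms}")
    hr = 60000.0 / pre_rr_ms
    if hr > tachy_bpm:
        return "tachycardia"
    if hr < brady_bpm:
        return "bradycardia"
    return "normal_rate"
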