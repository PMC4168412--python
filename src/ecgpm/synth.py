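"""Seeded synthetic single-lead ECG with ground-truth beat annotations.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative
to the R apex; beat-to-beat timing varies by a Gaussian RR jitter.  A
minority class of PVC-like abnormal beats is morphologically distinct:
absent P wave, a wide and taller R (width x3, amplitude x1.3), inverted T,
and premature timing (preceding RR scaled by 0.7 by default).  Optional
additive noise covers the three usual contaminants: white noise at a given
SNR, low-frequency baseline wander, and mains interference.  The signal
is digitized to a 10-bit ADC range, and the R sample index plus label of
every beat is attached as ground truth, making the generator the oracle
for every downstream stage.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatAnnotation, ECGRecord

__all__ = ["SynthConfig", "generate"]

# Gaussian bump parameters per wave: (amplitude mV, center ms rel. R, width ms)
_NORMAL_WAVES = {
    "P": (0.15, -160.0, 22.0),
    "Q": (-0.10, -28.0, 9.0),
    "R": (1.00, 0.0, 11.0),
    "S": (-0.22, 30.0, 9.0),
    "T": (0.35, 220.0, 55.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give a clean 72 bpm adult rhythm."""

    fs: float = 360.0
    duration_s: float = 60.0
    mean_hr_bpm: float = 72.0
    rr_sd_ms: float = 30.0
    abnormal_rate: float = 0.05
    abnormal_prematurity: float = 0.7
    white_snr_db: float | None = None   # None = no white noise
    baseline_amp_mv: float = 0.0
    baseline_hz: float = 0.3
    mains_amp_mv: float = 0.0
    mains_hz: float = 60.0
    adc_bits: int = 10
    adc_range_mv: tuple[float, float] = (-1.6, 2.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.abnormal_rate <= 1:
            raise ValueError("abnormal_rate must lie in [0, 1]")
        if self.fs <= 2 * self.mains_hz:
            raise ValueError("fs must exceed twice the mains frequency")
        if self.duration_s <= 0 or self.mean_hr_bpm <= 0:
            raise ValueError("duration_s and mean_hr_bpm must be positive")


def _beat_waveform(t_ms: np.ndarray, abnormal: bool) -> np.ndarray:
    """Sum of Gaussian bumps evaluated at times t_ms relative to the R apex."""
    y = np.zeros_like(t_ms)
    for wave, (amp, center, width) in _NORMAL_WAVES.items():
        if abnormal:
            if wave == "P":
                continue                      # absent P wave
            if wave == "R":
                amp, width = amp * 1.3, width * 3.0   # wide, tall QRS
            if wave == "T":
                amp = -amp                    # inverted T
        y += amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return y


def generate(config: SynthConfig) -> ECGRecord:
    """Render the configured rhythm into a quantized, annotated ECGRecord."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs

    mean_rr = 60000.0 / config.mean_hr_bpm
    # Draw beat times: start a little inside the record so the first PQRST
    # window fits; abnormal beats are premature (shorter preceding RR).
    r_times: list[float] = [300.0]
    labels: list[str] = ["normal"]
    while True:
        rr = rng.normal(mean_rr, config.rr_sd_ms)
        rr = max(rr, 0.4 * mean_rr)
        abnormal = rng.random() < config.abnormal_rate
        if abnormal:
            rr *= config.abnormal_prematurity
        t_next = r_times[-1] + rr
        if t_next >= t_ms[-1] - 400.0:
            break
        r_times.append(t_next)
        labels.append("abnormal" if abnormal else "normal")
    # first beat's class is drawn like the rest (it just has no RR to shorten)
    if rng.random() < config.abnormal_rate:
        labels[0] = "abnormal"

    y = np.zeros(n)
    for rt, lab in zip(r_times, labels):
        # evaluate each bump only on a local support to keep this linear in n
        lo = max(0, int((rt - 350.0) * fs / 1000))
        hi = min(n, int((rt + 450.0) * fs / 1000) + 1)
        y[lo:hi] += _beat_waveform(t_ms[lo:hi] - rt, lab == "abnormal")

    if config.baseline_amp_mv:
        y += config.baseline_amp_mv * np.sin(
            2 * np.pi * config.baseline_hz * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi)
        )
    if config.mains_amp_mv:
        y += config.mains_amp_mv * np.sin(
            2 * np.pi * config.mains_hz * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi)
        )
    if config.white_snr_db is not None:
        sig_rms = float(np.sqrt(np.mean(y**2)))
        noise_rms = sig_rms / 10 ** (config.white_snr_db / 20)
        y += rng.normal(0.0, noise_rms, size=n)

    lo_mv, hi_mv = config.adc_range_mv
    levels = 2**config.adc_bits - 1
    adc = np.rint((np.clip(y, lo_mv, hi_mv) - lo_mv) / (hi_mv - lo_mv) * levels)

    anns = [
        BeatAnnotation(sample_index=int(round(rt * fs / 1000)), label=lab)  # type: ignore[arg-type]
        for rt, lab in zip(r_times, labels)
    ]
    return ECGRecord(
        samples=adc, fs=fs, units="adc", annotations=anns, adc_bits=config.adc_bits
    )
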