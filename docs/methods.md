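# Methods

## Problem setting

A wearable single-lead ECG transmitter has tight bandwidth and memory
budgets. The package implements a transmit-side screen that classifies
each heartbeat as morphologically normal or abnormal against a template
learned from the wearer's own first 30 seconds of rhythm, and a codec
that sends full waveform data only for abnormal beats. Everything is
designed to be implementable on a small microcontroller: integer
occupancy counts, fixed windows, no per-beat optimisation.

## R-peak detection

The chain is low-pass filter → moving average → first difference →
square → energy integration → adaptive threshold.

* **Low-pass, 35 Hz.** Realised as a 4th-order Butterworth applied
  forward–backward (zero phase), so R-peak indices are not shifted and
  the DC gain is exactly 1. Zero-phase filtering uses future samples; a
  strictly causal deployment would substitute a causal filter and accept
  a constant group delay.
* **Moving average.** Causal boxcar, default width `round(fs/60)`
  samples, which places a spectral null exactly on 60 Hz mains
  (`round(fs/50)` for 50 Hz regions). Edges average the available
  prefix; width 1 is the identity.
* **First difference.** `y[n] = x[n] − x[n−1]`, `y[0] = 0`.
* **Energy integration.** The squared difference is summed over a 150 ms
  boxcar (a moving-window integrator at QRS scale). This step exists
  because a threshold on the squared derivative alone systematically
  misses wide, low-slope ventricular beats: a PVC-like complex with
  3× the QRS width and 1.3× the amplitude has a squared-derivative peak
  of only ≈ 0.19× a normal beat's, below any usable fraction of the
  running maximum, whereas its slope²-×-duration energy is ≈ 0.56× — 
  comfortably above the 0.5 threshold fraction. Integrating energy
  weights narrow and wide complexes nearly equally and is the standard
  remedy in derivative-based QRS detectors.
* **Variable threshold.** A candidate is a local maximum of the energy
  exceeding `thr_fraction` (default 0.5) times the running maximum of
  the energy over the trailing 2 s. An absolute floor of
  `(1e-7 · max|x|)² · window` ignores numerical residue on
  near-constant signals. Candidates within the 200 ms refractory period
  of a stronger candidate are suppressed.
* **Refinement.** Each accepted candidate moves to the apex of the
  low-pass-filtered ECG within ±50 ms, so RR intervals (preRR) are
  measured between true R apices rather than energy maxima.

Defaults: cutoff 35 Hz, refractory 200 ms, threshold fraction 0.5,
threshold window 2 s, energy window 150 ms. All are exposed on
`RPeakParams` and as CLI flags.

## Beat windowing and quantization

The PQRST window runs from 220 ms before to 380 ms after the R peak
(`ceil` at non-integral sample counts); at 360 Hz that is 80 + 1 + 137 =
218 samples, at 250 Hz 55 + 1 + 95 = 151. Windows that would cross a
record boundary are dropped with a logged warning — in streaming use an
edge beat is simply skipped, never fatal.

Each window is min–max quantized to A = 81 amplitude rows:
`row[i] = round((x[i] − min)/(max − min) · 80)`; a degenerate constant
window maps to the middle row. Per-beat normalization makes the match
tolerant to slow gain and baseline drift; a fixed-range mode would make
it sensitive to amplitude change, which is arguably diagnostic signal,
but the per-beat choice is the default because wearable electrodes drift
constantly.

**Matching domain.** Both training and matching quantize windows taken
from the 35 Hz low-pass-filtered signal, not the raw samples. With
per-beat min–max scaling, wideband noise on the window extremes shifts
the whole trajectory coherently; at 20 dB SNR this pushed ≈ 11% of
genuinely normal beats below the classification threshold. Matching on
the band-limited signal — which is also what a hardware front end would
present — removes that failure mode (mis-rate ≈ 0.6% at 20 dB) without
touching the transmitted payloads, which stay raw.

## Pattern matrix, ratePM, classification

Training starts from an all-zero 218 × 81 grid. For every training beat
and column `i`, cells `(i, row)`, `(i, row−1)`, `(i, row+1)` are each
incremented if currently below the cap of 10; neighbour rows outside the
grid are skipped. The ±1 smear builds amplitude tolerance directly into
the template. Training is order-independent wherever no cell saturates.

`ratePM` counts the columns of an incoming quantized beat whose visited
cell holds a count **greater than 7** — i.e. the column lies on a part of
the template supported by at least 8 training passes. Matching tests
only the exact cell (no ±1 look-around), because training already
smeared ±1; smearing both sides would double the tolerance band.

`ratePM > 180` classifies the beat normal; `ratePM ≤ 180` abnormal (the
boundary value counts as abnormal — the conservative choice for a
screen). The threshold, the cap and A are all configurable; an
evaluation preset (`--preset mitbih`) switches the threshold to 35,
suited to screening annotated ambulatory records where beat-to-beat
variability is much higher than in a 30 s self-trained span.

The stored reconstruction template is the element-wise mean of the raw
training windows — averaging also suppresses training-time noise by
roughly the square root of the number of beats.

## Packet codec

Little-endian layouts: `T` = `0x54, fs:u16, len:u16, samples` (5 + 2·len
bytes); `N` = `0x4E, preRR:u16, ratePM:u8` (4 bytes); `A` = `0x41,
preRR:u16, ratePM:u8, len:u16, samples` (6 + 2·len bytes). Samples
travel as 10-bit ADC counts in a u16 each; mV input is affinely mapped
onto 0–1023 using the training-span range (the map is carried on the
in-memory stream object; reconstruction and the fidelity metrics are
scale-invariant, so the map need not cross the wire). Lengths are
self-describing, so any prefix of a valid stream decodes to a prefix of
the packet list and no resynchronization logic is needed. preRR is
transmitted in milliseconds (u16 covers RR up to 65.5 s). No checksum:
link-layer integrity is delegated to the transport.

The template is sent once, first. Swapping one normal beat for an
abnormal one grows the stream by exactly 438 bytes at 218-sample
windows.

## Reconstruction

Beat k's window (template for `N`, payload for `A`) is placed with its R
sample at `anchor + Σ round(preRR_j · fs/1000)`. Gaps between adjacent
windows are bridged by linear interpolation between the neighbouring
edge samples — continuity without inventing morphology. When a premature
beat's window overlaps its predecessor, the later window overwrites from
its first sample, so transmitted abnormal waveforms always display
verbatim.

## Metrics

* **CR** = raw bytes / transmitted bytes, with raw counted at 2 bytes
  per 10-bit sample over the transmitted span.
* **CC / RMSE**: both signals min–max normalized to [0, 1] over the
  compared span, then Pearson r and root-mean-square difference. The
  normalization puts RMSE on a 0–1 scale regardless of input units.
* **R-peak accuracy**: greedy one-to-one pairing of detections to
  reference beats within ±50 ms; matched / reference · 100.
* **Abnormal accuracy**: reference-abnormal beats paired with a beat
  classified `A`, divided by reference-abnormal count; false alarms
  (reference-normal classified `A`) are reported separately rather than
  folded into the ratio, so over-detection cannot inflate the score.

## Synthetic generator

Each beat is a sum of five Gaussian bumps; defaults (amplitude mV,
centre ms relative to R, width ms): P (0.15, −160, 22), Q (−0.10, −28,
9), R (1.00, 0, 11), S (−0.22, 30, 9), T (0.35, 220, 55). RR intervals
are Gaussian around 60000/HR with 30 ms jitter (floored at 0.4× the
mean). Abnormal beats are PVC-like: no P wave, R width ×3 and amplitude
×1.3, inverted T, preceding RR ×0.7. Optional noise: white at a given
SNR (relative to signal RMS), baseline-wander and mains sinusoids with
random phase. The signal is clipped and quantized to a 10-bit ADC over
−1.6 to +2.4 mV, and every beat's R sample index and label are attached
as ground truth. Defaults: 360 Hz, 72 bpm, 5% abnormal, no noise.

What it does *not* emulate: physiologic HRV spectra and respiratory
modulation, electrode motion artifacts, ectopic morphology diversity
(all PVC-like beats share one shape family), atrial arrhythmias without
morphology change, and compensatory pauses. Consequently, passing
recovery tests on synthetic streams demonstrates the mechanics of the
method under controlled morphology separation and additive noise — not
clinical detection performance on ambulatory recordings, which depends
on unmodeled beat-class overlap.

## Problem sizes and numerical choices

Test and acceptance runs use 60–455 s synthetic records (up to ~520
beats per stream, ten seeds) — large enough for stable class rates,
small enough to iterate quickly. Ties in quantization round half away
from zero via `np.rint`'s banker-free behaviour on .5 offsets is not
relied upon anywhere; trajectory comparisons are exact-integer. The
codec is bit-exact by construction and tested over 10⁴ random packets.

## Known limitations

* The zero-phase low-pass and the ±50 ms apex refinement use future
  samples; an embedded port would re-introduce a fixed latency.
* One template per wearer per session: the matrix is not adapted over
  time, so slow morphology drift (position change, electrode migration)
  will raise false alarms until retraining.
* The binary normal/abnormal collapse discards arrhythmia subtype
  information by design.
* The WFDB reader covers headers, signal formats 16 and 212 and MIT
  annotation files only — enough for the classic ambulatory databases,
  not the full format family.
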