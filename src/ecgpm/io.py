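"""Reading and writing single-lead ECG signals and beat annotations.

Supported formats:

* a minimal subset of the PhysioNet WFDB format — the plain-text ``.hea``
  header, signal formats 16 (int16 little-endian) and 212 (packed 12-bit
  pairs, the MIT-BIH on-disk format), and MIT-format ``.atr`` beat
  annotation files;
* single-column CSV sample streams with a caller-supplied sampling rate.

Beat annotation codes are collapsed to a binary normal/abnormal label:
the WFDB NORMAL code maps to ``normal``, every other *beat* code (PVC,
APC, fusion, paced, escape, bundle-branch block, ...) maps to
``abnormal``, and non-beat codes (rhythm changes, artifacts, comments)
are dropped.  This matches a screening use-case where the question is
"does this beat look like the subject's normal beats", not which
arrhythmia it is.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "BeatAnnotation",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_signal",
    "write_csv",
]

# MIT annotation code numbers -> mnemonic, restricted to *beat* codes.
# Non-beat codes (rhythm '+', quality '~', note '"', etc.) are absent and
# therefore dropped during the normal/abnormal collapse.
_BEAT_CODES: dict[int, str] = {
    1: "N",   # normal
    2: "L",   # left bundle branch block
    3: "R",   # right bundle branch block
    4: "a",   # aberrated atrial premature
    5: "V",   # premature ventricular contraction
    6: "F",   # fusion of ventricular and normal
    7: "J",   # nodal (junctional) premature
    8: "A",   # atrial premature
    9: "S",   # supraventricular premature
    10: "E",  # ventricular escape
    11: "j",  # nodal escape
    12: "/",  # paced
    13: "Q",  # unclassifiable
    34: "e",  # atrial escape
    38: "f",  # fusion of paced and normal
}
_CODE_FOR_MNEMONIC = {v: k for k, v in _BEAT_CODES.items()}
# '.' is an alternate mnemonic for the normal beat code in older files.
_CODE_FOR_MNEMONIC["."] = 1

_NORMAL_MNEMONICS = frozenset({"N", "."})


@dataclass(frozen=True)
class BeatAnnotation:
    """A reference heartbeat: R-peak sample index plus a binary label."""

    sample_index: int
    label: Literal["normal", "abnormal"]


@dataclass
class ECGRecord:
    """A sampled single-lead ECG.

    Parameters
    ----------
    samples : array-like
        Amplitude values, either raw ADC counts or physical millivolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    units : {"adc", "mV"}
        Interpretation of ``samples``.  ADC data is validated against the
        ``adc_bits`` range (10-bit -> 0..1023).
    annotations : list of BeatAnnotation, optional
        Reference beats sorted by sample index.
    adc_bits : int
        ADC resolution used to validate ``units == "adc"`` data.
    """

    samples: np.ndarray
    fs: float
    units: Literal["adc", "mV"] = "adc"
    annotations: list[BeatAnnotation] | None = None
    adc_bits: int = 10

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.units not in ("adc", "mV"):
            raise ValueError(f"units must be 'adc' or 'mV', got {self.units!r}")
        if self.units == "adc":
            hi = 2**self.adc_bits - 1
            if self.samples.min() < 0 or self.samples.max() > hi:
                raise ValueError(
                    f"adc samples must lie in [0, {hi}] "
                    f"(got [{self.samples.min()}, {self.samples.max()}])"
                )
        if self.annotations:
            idx = [a.sample_index for a in self.annotations]
            if any(i < 0 or i >= len(self.samples) for i in idx):
                raise ValueError("annotation sample_index out of record bounds")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("annotations must be sorted ascending")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


def collapse_beat_label(mnemonic: str) -> str | None:
    """Map a WFDB annotation mnemonic to 'normal'/'abnormal' (None = non-beat)."""
    if mnemonic in _NORMAL_MNEMONICS:
        return "normal"
    if mnemonic in _CODE_FOR_MNEMONIC:
        return "abnormal"
    return None


# ---------------------------------------------------------------------------
# WFDB subset
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise IOError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    nsamp = int(head[3]) if len(head) > 3 else 0
    sigs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_s, base_s = gain_part.rstrip(")").split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain, baseline = float(gain_part), 0
        if gain == 0:
            gain = 200.0
        sigs.append({"file": f[0], "fmt": int(fmt), "gain": gain, "baseline": baseline})
    if len(sigs) != nsig:
        raise IOError(f"WFDB header {hea_path} declares {nsig} signals, found {len(sigs)}")
    return name, nsig, fs, nsamp, sigs


def _read_dat(dat_path: Path, fmt: int, nsig: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        vals = np.frombuffer(raw, dtype="<i2").astype(int)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)]
        triplets = b.reshape(-1, 3).astype(int)
        first = triplets[:, 0] | ((triplets[:, 1] & 0x0F) << 8)
        second = triplets[:, 2] | ((triplets[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        vals = np.empty(2 * len(triplets), dtype=int)
        vals[0::2] = first
        vals[1::2] = second
    else:
        raise IOError(f"unsupported WFDB signal format {fmt} in {dat_path}")
    n = nsig * (len(vals) // nsig)
    return vals[:n].reshape(-1, nsig)


def _read_annotations(atr_path: Path, n_samples: int) -> list[BeatAnnotation]:
    raw = atr_path.read_bytes()
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval follows
            if i + 3 >= len(raw):
                break
            t += struct.unpack("<i", bytes([raw[i + 2], raw[i + 3], raw[i], raw[i + 1]]))[0]
            i += 4
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN: no time advance
            continue
        if code == 63:  # AUX: skip payload (padded to even length)
            i += interval + (interval & 1)
            continue
        t += interval
        mnemonic = _BEAT_CODES.get(code)
        if mnemonic is None:
            continue  # non-beat annotation
        label = collapse_beat_label(mnemonic)
        if label is not None and 0 <= t < n_samples:
            out.append(BeatAnnotation(sample_index=t, label=label))
    return out


def read_wfdb_record(path: str | Path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record (``path`` without extension).

    Samples are returned as raw ADC counts (``units='adc'``) when they are
    non-negative, with the ADC resolution inferred from the data range;
    signed data is converted to physical millivolts via the header's
    gain/baseline.  If a ``.atr`` annotation file sits next to the record
    its beat annotations are loaded and collapsed to normal/abnormal.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header file: {hea}")
    name, nsig, fs, nsamp, sigs = _parse_header(hea)
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig}-signal record")
    dat = base.parent / sigs[channel]["file"]
    if not dat.exists():
        raise IOError(f"missing WFDB signal file: {dat}")
    mat = _read_dat(dat, sigs[channel]["fmt"], nsig)
    x = mat[:, channel].astype(float)
    if nsamp:
        x = x[:nsamp]
    atr = base.with_suffix(".atr")
    anns = _read_annotations(atr, len(x)) if atr.exists() else None
    if x.min() >= 0:
        bits = 10 if x.max() <= 1023 else (11 if x.max() <= 2047 else 12)
        return ECGRecord(samples=x, fs=fs, units="adc", annotations=anns, adc_bits=bits)
    sig = sigs[channel]
    mv = (x - sig["baseline"]) / sig["gain"]
    return ECGRecord(samples=mv, fs=fs, units="mV", annotations=anns)


def write_wfdb_record(
    record: ECGRecord,
    path: str | Path,
    annotations: Sequence[tuple[int, str]] | None = None,
) -> Path:
    """Write ``record`` as a format-16 WFDB record (plus ``.atr`` if asked).

    ``annotations`` is an optional list of ``(sample_index, mnemonic)``
    pairs, e.g. ``[(100, 'N'), (460, 'V')]``.  Intended for test fixtures
    and interchange; ADC units only.
    """
    base = Path(path)
    name = base.name
    vals = np.rint(record.samples).astype("<i2")
    (base.parent / f"{name}.dat").write_bytes(vals.tobytes())
    hdr = (
        f"{name} 1 {record.fs:g} {len(vals)}\n"
        f"{name}.dat 16 200 {record.adc_bits + 1} 0 {int(vals[0])} 0 0 ECG\n"
    )
    (base.parent / f"{name}.hea").write_text(hdr)
    if annotations is not None:
        buf = bytearray()
        prev = 0
        for idx, mnem in annotations:
            code = _CODE_FOR_MNEMONIC.get(mnem)
            if code is None:
                raise ValueError(f"unknown beat mnemonic {mnem!r}")
            dt = idx - prev
            if dt < 0:
                raise ValueError("annotations must be sorted ascending")
            while dt > 1023:  # SKIP chunk for long gaps
                word = 59 << 10
                buf += struct.pack("<H", word)
                chunk = min(dt, 2**31 - 1)
                hi, lo = divmod(chunk, 1 << 16)
                buf += struct.pack("<HH", hi, lo)
                dt -= chunk
            buf += struct.pack("<H", (code << 10) | dt)
            prev = idx
        buf += struct.pack("<H", 0)
        (base.parent / f"{name}.atr").write_bytes(bytes(buf))
    return base


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def read_csv_signal(path: str | Path, fs: float, units: str = "adc") -> ECGRecord:
    """Read a one-column numeric CSV into an ECGRecord (no annotations)."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s.split(",")[0]))
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric value {s!r}") from None
    if not values:
        raise ValueError(f"{path}: no numeric samples found")
    return ECGRecord(samples=np.array(values), fs=fs, units=units)  # type: ignore[arg-type]


def write_csv(record: ECGRecord, path: str | Path) -> Path:
    """Write one sample per line; integers exactly, floats to 9 sig. digits."""
    path = Path(path)
    x = record.samples
    if np.allclose(x, np.rint(x)):
        lines = (str(int(v)) for v in np.rint(x).astype(int))
    else:
        lines = (format(v, ".9g") for v in x)
    path.write_text("\n".join(lines) + "\n")
    return path
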