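"""Variable-payload packet codec for ECG telemetry.

The stream starts with a single template packet (kind ``T``) carrying the
sampling rate and the trained normal-beat template.  After that, every
detected beat produces either a 4-byte normal message (kind ``N``: beat
type, preRR, ratePM — no waveform) or a full abnormal message (kind
``A``: header plus the beat's raw PQRST window).  Sending waveform data
only for abnormal beats is what buys the large compression ratios.

Wire layout (little-endian, lengths self-describing so decoding never
needs resynchronization):

====  =======================================================  =========
kind  layout                                                   bytes
====  =======================================================  =========
T     0x54, fs:u16, len:u16, len x u16 samples                 5 + 2*len
N     0x4E, preRR:u16, ratePM:u8                               4
A     0x41, preRR:u16, ratePM:u8, len:u16, len x u16 samples   6 + 2*len
====  =======================================================  =========

Samples on the wire are raw 10-bit ADC counts in a u16 each; mV input is
affinely mapped onto 0–1023 (the map is carried on the PacketStream
object, not on the wire — the receiver reconstructs in ADC units).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ECGRecord
from .pattern import (
    PatternMatrix,
    WindowSpec,
    classify_beat,
    compute_rate_pm,
    extract_pqrst,
    quantize_beat,
)
from .rpeak import RPeakParams, detect_rpeaks

__all__ = [
    "Packet",
    "PacketStream",
    "encode_packet",
    "decode_packet",
    "encode_stream",
    "decode_stream",
    "generate_stream",
]

_KIND_BYTE = {"T": 0x54, "N": 0x4E, "A": 0x41}
_BYTE_KIND = {v: k for k, v in _KIND_BYTE.items()}
ADC_MAX = 1023


class FramingError(ValueError):
    """Raised when a byte buffer cannot be parsed as a packet stream."""


@dataclass
class Packet:
    """One wire message: template (T), normal beat (N) or abnormal beat (A)."""

    kind: str                        # 'T' | 'N' | 'A'
    pre_rr_ms: int | None = None     # N, A
    rate_pm: int | None = None       # N, A
    payload: np.ndarray | None = None  # T: template; A: beat window
    fs: float | None = None          # T only

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Packet):
            return NotImplemented
        if (self.kind, self.pre_rr_ms, self.rate_pm, self.fs) != (
            other.kind, other.pre_rr_ms, other.rate_pm, other.fs
        ):
            return False
        a = self.payload if self.payload is not None else np.empty(0)
        b = other.payload if other.payload is not None else np.empty(0)
        return len(a) == len(b) and bool(np.all(np.asarray(a) == np.asarray(b)))


@dataclass
class PacketStream:
    """An ordered packet sequence plus its total encoded byte size."""

    packets: list[Packet]
    byte_size: int
    # affine map applied to mV input before 10-bit quantization: adc = x*scale + offset
    mv_scale: float = 1.0
    mv_offset: float = 0.0
    # transmitter-side bookkeeping (not on the wire): original-time-base
    # sample index of the first transmitted beat's R peak
    first_r_index: int | None = None

    def __len__(self) -> int:
        return len(self.packets)


def _check_samples(x: np.ndarray) -> np.ndarray:
    v = np.rint(np.asarray(x)).astype(int)
    if v.size and (v.min() < 0 or v.max() > ADC_MAX):
        raise ValueError(
            f"payload samples outside 0..{ADC_MAX} after mapping "
            f"(got [{v.min()}, {v.max()}])"
        )
    return v


def encode_packet(p: Packet) -> bytes:
    """Serialize one packet to its little-endian wire form."""
    if p.kind == "N":
        if p.pre_rr_ms is None or p.rate_pm is None:
            raise ValueError("N packet needs pre_rr_ms and rate_pm")
        if not 0 <= p.pre_rr_ms <= 0xFFFF:
            raise ValueError(f"preRR {p.pre_rr_ms} ms does not fit in u16")
        return struct.pack("<BHB", 0x4E, p.pre_rr_ms, p.rate_pm)
    if p.kind == "A":
        if p.pre_rr_ms is None or p.rate_pm is None or p.payload is None:
            raise ValueError("A packet needs pre_rr_ms, rate_pm and payload")
        if not 0 <= p.pre_rr_ms <= 0xFFFF:
            raise ValueError(f"preRR {p.pre_rr_ms} ms does not fit in u16")
        v = _check_samples(p.payload)
        return (
            struct.pack("<BHBH", 0x41, p.pre_rr_ms, p.rate_pm, len(v))
            + v.astype("<u2").tobytes()
        )
    if p.kind == "T":
        if p.fs is None or p.payload is None:
            raise ValueError("T packet needs fs and payload")
        v = _check_samples(p.payload)
        return (
            struct.pack("<BHH", 0x54, int(round(p.fs)), len(v))
            + v.astype("<u2").tobytes()
        )
    raise ValueError(f"unknown packet kind {p.kind!r}")


def decode_packet(buf: bytes, offset: int = 0) -> tuple[Packet, int]:
    """Parse one packet starting at ``offset``; returns (packet, next_offset)."""
    if offset >= len(buf):
        raise FramingError(f"offset {offset} beyond buffer end")
    kind = _BYTE_KIND.get(buf[offset])
    if kind is None:
        raise FramingError(f"unknown packet kind byte 0x{buf[offset]:02X} at offset {offset}")
    try:
        if kind == "N":
            pre_rr, rate = struct.unpack_from("<HB", buf, offset + 1)
            return Packet(kind="N", pre_rr_ms=pre_rr, rate_pm=rate), offset + 4
        if kind == "A":
            pre_rr, rate, n = struct.unpack_from("<HBH", buf, offset + 1)
            end = offset + 6 + 2 * n
            if end > len(buf):
                raise FramingError(f"truncated A packet at offset {offset}")
            payload = np.frombuffer(buf[offset + 6 : end], dtype="<u2").astype(int)
            return Packet(kind="A", pre_rr_ms=pre_rr, rate_pm=rate, payload=payload), end
        fs, n = struct.unpack_from("<HH", buf, offset + 1)
        end = offset + 5 + 2 * n
        if end > len(buf):
            raise FramingError(f"truncated T packet at offset {offset}")
        payload = np.frombuffer(buf[offset + 5 : end], dtype="<u2").astype(int)
        return Packet(kind="T", fs=float(fs), payload=payload), end
    except struct.error as e:
        raise FramingError(f"truncated packet at offset {offset}: {e}") from None


def encode_stream(stream: PacketStream) -> bytes:
    return b"".join(encode_packet(p) for p in stream.packets)


def decode_stream(buf: bytes) -> PacketStream:
    packets: list[Packet] = []
    off = 0
    while off < len(buf):
        p, off = decode_packet(buf, off)
        packets.append(p)
    return PacketStream(packets=packets, byte_size=len(buf))


def _mv_map(record: ECGRecord, template: np.ndarray) -> tuple[float, float]:
    """Affine map putting a mV record's observed range onto 0..ADC_MAX."""
    lo = float(min(record.samples.min(), template.min()))
    hi = float(max(record.samples.max(), template.max()))
    if hi == lo:
        return 1.0, ADC_MAX / 2 - lo
    scale = ADC_MAX / (hi - lo)
    return scale, -lo * scale


def generate_stream(
    record: ECGRecord,
    matrix: PatternMatrix,
    skip_seconds: float = 30.0,
    params: RPeakParams | None = None,
    spec: WindowSpec | None = None,
    threshold: int | None = None,
) -> PacketStream:
    """Detect, classify and packetize every beat after the training span.

    Emits the T packet first, then per beat an N or A packet; beats whose
    PQRST window does not fit inside the record are skipped.
    """
    if matrix.trained_beats < 1:
        raise ValueError("pattern matrix is untrained")
    spec = spec or WindowSpec(fs=record.fs)
    thr = matrix.classify_threshold if threshold is None else threshold

    if record.units == "mV":
        scale, offset = _mv_map(record, matrix.template)
    else:
        scale, offset = 1.0, 0.0
    to_adc = lambda x: np.clip(np.rint(np.asarray(x) * scale + offset), 0, ADC_MAX).astype(int)

    packets = [Packet(kind="T", fs=record.fs, payload=to_adc(matrix.template))]
    result = detect_rpeaks(record, params)
    # quantized trajectories come from the band-limited signal (same choice
    # as training); transmitted waveforms stay raw
    from .rpeak import lowpass_filter

    cutoff = (params or RPeakParams()).lp_cutoff
    filtered = lowpass_filter(record, cutoff)
    n_skip = int(round(skip_seconds * record.fs))
    prev_peak: int | None = None
    first_r: int | None = None
    for i, r in enumerate(result.peaks):
        if r < n_skip:
            prev_peak = int(r)
            continue
        w = extract_pqrst(record, int(r), spec)
        w_flt = extract_pqrst(filtered, int(r), spec)
        if w is None or w_flt is None:
            continue
        beat = quantize_beat(w_flt, matrix.a_rows, r_index=int(r))
        if first_r is None:
            first_r = int(r)
        rate = compute_rate_pm(matrix, beat)
        pre_rr = 0 if prev_peak is None else int(round((r - prev_peak) * 1000 / record.fs))
        pre_rr = min(pre_rr, 0xFFFF)
        if classify_beat(rate, thr) == "N":
            packets.append(Packet(kind="N", pre_rr_ms=pre_rr, rate_pm=min(rate, 255)))
        else:
            packets.append(
                Packet(kind="A", pre_rr_ms=pre_rr, rate_pm=min(rate, 255), payload=to_adc(w))
            )
        prev_peak = int(r)
    stream = PacketStream(
        packets=packets, byte_size=0, mv_scale=scale, mv_offset=offset,
        first_r_index=first_r,
    )
    stream.byte_size = len(encode_stream(stream))
    return stream


def write_stream(stream: PacketStream, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(encode_stream(stream))
    return path


def read_stream(path: str | Path) -> PacketStream:
    return decode_stream(Path(path).read_bytes())
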