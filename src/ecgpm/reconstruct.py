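"""Receiver-side ECG reconstruction from a packet stream.

Normal beats are rendered by replaying the stored template; abnormal
beats are rendered from their transmitted waveform.  Beat k's R sample is
placed at ``anchor + sum(preRR_j * fs / 1000)`` over the beats received so
far, gaps between adjacent windows are bridged by linear interpolation
between the neighbouring edge samples, and when a premature beat's window
overlaps its predecessor the later window overwrites from its first
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .packets import PacketStream
from .pattern import WindowSpec

__all__ = ["ReconstructedSignal", "reconstruct"]


@dataclass
class ReconstructedSignal:
    """Reconstruction on the transmitter's time base, plus a per-beat log."""

    samples: np.ndarray
    fs: float
    beat_log: list[tuple[str, int, int]]  # (kind, r_position, ratePM)

    def __len__(self) -> int:
        return len(self.samples)


def reconstruct(
    stream: PacketStream,
    anchor: int = 0,
    spec: WindowSpec | None = None,
) -> ReconstructedSignal:
    """Rebuild the signal described by ``stream``.

    ``anchor`` is the sample index at which the first received beat's R
    peak is placed (the transmitter's first post-training beat position,
    when known, puts the reconstruction on the original time base).
    """
    if not stream.packets or stream.packets[0].kind != "T":
        raise ValueError("packet stream must begin with a template (T) packet")
    tpkt = stream.packets[0]
    fs = float(tpkt.fs)
    template = np.asarray(tpkt.payload, dtype=float)
    spec = spec or WindowSpec(fs=fs)
    n_pre = spec.n_pre

    beats = stream.packets[1:]
    if not beats:
        return ReconstructedSignal(samples=template.copy(), fs=fs, beat_log=[])

    # R positions from cumulative preRR; the first beat sits at the anchor.
    r_pos: list[int] = []
    pos = anchor
    for i, p in enumerate(beats):
        if p.kind not in ("N", "A"):
            raise ValueError(f"unexpected packet kind {p.kind!r} mid-stream")
        if i > 0:
            pos += int(round(p.pre_rr_ms * fs / 1000))
        r_pos.append(pos)

    windows = [
        template if p.kind == "N" else np.asarray(p.payload, dtype=float)
        for p in beats
    ]
    total = r_pos[-1] - n_pre + len(windows[-1])
    out = np.zeros(max(total, r_pos[0] - n_pre + len(windows[0])))
    filled = np.zeros(len(out), dtype=bool)

    prev_end = None  # index just past the previous window
    for pos, win in zip(r_pos, windows):
        start = pos - n_pre
        if start < 0:  # anchor too small to fit the first pre-R segment
            win = win[-start:]
            start = 0
        end = start + len(win)
        out[start:end] = win
        filled[start:end] = True
        if prev_end is not None and start > prev_end:
            # linear bridge between the previous window's last sample and
            # this window's first sample
            left, right = out[prev_end - 1], win[0]
            gap = start - prev_end
            out[prev_end:start] = left + (right - left) * (
                np.arange(1, gap + 1) / (gap + 1)
            )
            filled[prev_end:start] = True
        prev_end = end

    log = [
        (p.kind, pos, int(p.rate_pm)) for p, pos in zip(beats, r_pos)
    ]
    return ReconstructedSignal(samples=out, fs=fs, beat_log=log)
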