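import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgpm import SynthConfig, generate
from ecgpm.packets import (
    FramingError,
    Packet,
    decode_packet,
    decode_stream,
    encode_packet,
    encode_stream,
    generate_stream,
)
from ecgpm.pattern import train_from_record


def random_packet(rng) -> Packet:
    kind = rng.choice(["T", "N", "A"])
    if kind == "N":
        return Packet(kind="N", pre_rr_ms=int(rng.integers(0, 65536)),
                      rate_pm=int(rng.integers(0, 256)))
    payload = rng.integers(0, 1024, size=int(rng.integers(1, 300)))
    if kind == "A":
        return Packet(kind="A", pre_rr_ms=int(rng.integers(0, 65536)),
                      rate_pm=int(rng.integers(0, 256)), payload=payload)
    return Packet(kind="T", fs=float(rng.integers(100, 1000)), payload=payload)


class TestLayout:
    def test_normal_packet_is_four_known_bytes(self):
        buf = encode_packet(Packet(kind="N", pre_rr_ms=800, rate_pm=210))
        assert buf == bytes([0x4E, 0x20, 0x03, 0xD2])

    def test_abnormal_packet_size(self):
        p = Packet(kind="A", pre_rr_ms=800, rate_pm=50,
                   payload=np.arange(218) % 1024)
        assert len(encode_packet(p)) == 6 + 2 * 218 == 442

    def test_template_packet_size(self):
        p = Packet(kind="T", fs=360, payload=np.arange(218) % 1024)
        assert len(encode_packet(p)) == 5 + 2 * 218 == 441

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            encode_packet(Packet(kind="N", pre_rr_ms=70000, rate_pm=1))
        with pytest.raises(ValueError):
            encode_packet(Packet(kind="A", pre_rr_ms=1, rate_pm=1,
                                 payload=np.array([2000])))


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(100))
    def test_random_packet_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        p = random_packet(rng)
        q, end = decode_packet(encode_packet(p))
        assert q == p and end == len(encode_packet(p))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_stream_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        packets = [random_packet(rng) for _ in range(rng.integers(1, 10))]
        from ecgpm.packets import PacketStream

        buf = encode_stream(PacketStream(packets=packets, byte_size=0))
        back = decode_stream(buf)
        assert back.packets == packets
        assert back.byte_size == len(buf)

    def test_prefix_of_stream_decodes_to_prefix_of_packets(self):
        rng = np.random.default_rng(7)
        packets = [random_packet(rng) for _ in range(5)]
        from ecgpm.packets import PacketStream

        buf = encode_stream(PacketStream(packets=packets, byte_size=0))
        # cut exactly at each packet boundary
        off = 0
        for k, p in enumerate(packets):
            off += len(encode_packet(p))
            assert decode_stream(buf[:off]).packets == packets[: k + 1]


class TestFraming:
    def test_unknown_kind_byte(self):
        with pytest.raises(FramingError, match="offset 0"):
            decode_packet(b"\xff\x00\x00\x00")

    def test_truncated_abnormal_packet(self):
        p = Packet(kind="A", pre_rr_ms=1, rate_pm=1, payload=np.arange(10))
        buf = encode_packet(p)
        with pytest.raises(FramingError):
            decode_packet(buf[:-1])

    def test_truncated_header(self):
        with pytest.raises(FramingError):
            decode_packet(b"\x4e\x01")


@pytest.fixture(scope="module")
def trained():
    rec = generate(SynthConfig(duration_s=120, abnormal_rate=0.0, seed=4))
    return rec, train_from_record(rec, 30.0)


class TestStreamGeneration:

    def test_all_normal_stream_byte_arithmetic(self, trained):
        rec, matrix = trained
        stream = generate_stream(rec, matrix, skip_seconds=30.0)
        kinds = [p.kind for p in stream.packets]
        assert kinds[0] == "T" and set(kinds[1:]) == {"N"}
        n_beats = len(kinds) - 1
        t_bytes = 5 + 2 * len(stream.packets[0].payload)
        assert stream.byte_size == t_bytes + 4 * n_beats

    def test_each_abnormal_beat_adds_438_bytes(self, trained):
        rec, matrix = trained
        base = generate_stream(rec, matrix, skip_seconds=30.0, threshold=0)
        # force every beat abnormal by an impossible threshold
        all_abn = generate_stream(rec, matrix, skip_seconds=30.0, threshold=218)
        n_beats = len(base.packets) - 1
        assert all_abn.byte_size - base.byte_size == 438 * n_beats

    def test_untrained_matrix_is_a_state_error(self, trained):
        rec, matrix = trained
        from ecgpm.pattern import PatternMatrix

        empty = PatternMatrix(
            cells=np.zeros_like(matrix.cells), a_rows=matrix.a_rows,
            trained_beats=0, template=matrix.template,
        )
        with pytest.raises(ValueError, match="untrained"):
            generate_stream(rec, empty)

    def test_no_beats_means_template_only(self):
        from ecgpm.io import ECGRecord
        from ecgpm.pattern import PatternMatrix

        flat = ECGRecord(samples=np.full(36000, 512.0), fs=360)
        m = PatternMatrix(
            cells=np.full((218, 81), 10, np.uint8), a_rows=81,
            trained_beats=5, template=np.full(218, 512.0),
        )
        stream = generate_stream(flat, m, skip_seconds=0.0)
        assert [p.kind for p in stream.packets] == ["T"]
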