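"""Whole-container streaming: chunking, round trips, size law, memory bound."""

import io

import pytest

from crypt4gh_stream import (
    CIPHER_SEGMENT_SIZE,
    SEGMENT_OVERHEAD,
    SEGMENT_SIZE,
    AuthenticationError,
    NoAccessError,
    TruncationError,
    decrypt_stream,
    encrypt_stream,
    generate_payload,
    rechunk,
    reencrypt_container,
    seeded_rng,
)

from .oracle import naive_apply_edit_list


def roundtrip(payload, writer, reader, rng, edit_list=None):
    container = io.BytesIO()
    enc = encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container,
                         edit_list=edit_list, rng=rng)
    container.seek(0)
    out = io.BytesIO()
    dec = decrypt_stream(container, reader, out)
    return out.getvalue(), enc, dec


class TestRechunk:
    def test_granularity_independence(self):
        data = generate_payload(1000, seed=4)
        dribble = (data[i : i + 7] for i in range(0, len(data), 7))
        assert list(rechunk(dribble, 16)) == list(rechunk(io.BytesIO(data), 16))

    def test_empty_source_yields_nothing(self):
        assert list(rechunk(io.BytesIO(b""), 16)) == []

    def test_final_chunk_unpadded(self):
        chunks = list(rechunk(io.BytesIO(bytes(SEGMENT_SIZE + 1)), SEGMENT_SIZE))
        assert [len(c) for c in chunks] == [SEGMENT_SIZE, 1]

    def test_lossless(self):
        data = generate_payload(12345, seed=5)
        assert b"".join(rechunk(io.BytesIO(data), 100)) == data

    def test_bad_size_rejected(self):
        with pytest.raises(ValueError):
            list(rechunk(io.BytesIO(b"x"), 0))


class TestRoundTrip:
    @pytest.mark.parametrize("size", [0, 1, 65535, 65536, 65537, 131072, 131073])
    def test_boundary_sizes(self, writer, reader, rng, size):
        payload = generate_payload(size, seed=size)
        got, enc, dec = roundtrip(payload, writer, reader, rng)
        assert got == payload
        assert dec.segments == enc.segments

    def test_segment_accounting(self, writer, reader, rng):
        payload = generate_payload(131072, seed=8)
        _, enc, _ = roundtrip(payload, writer, reader, rng)
        assert enc.segments == 2
        assert enc.bytes_out - enc.header_length == 2 * CIPHER_SEGMENT_SIZE == 131128

    def test_one_extra_byte_adds_29_wire_bytes(self, writer, reader, rng):
        payload = generate_payload(131073, seed=8)
        _, enc, _ = roundtrip(payload, writer, reader, rng)
        assert enc.segments == 3
        assert enc.bytes_out - enc.header_length == 2 * CIPHER_SEGMENT_SIZE + 1 + SEGMENT_OVERHEAD

    def test_empty_payload_header_only(self, writer, reader, rng):
        got, enc, _ = roundtrip(b"", writer, reader, rng)
        assert got == b"" and enc.segments == 0
        assert enc.bytes_out == enc.header_length

    def test_trailing_empty_segment_accepted(self, writer, reader, rng):
        # When the plaintext is an exact multiple of the segment size, some
        # writers emit a final 28-byte segment decrypting to b""; accept it.
        container = io.BytesIO()
        data_key_rng = seeded_rng(99)
        payload = generate_payload(SEGMENT_SIZE, seed=1)
        encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container, rng=rng)
        from crypt4gh_stream.header import parse_header
        from crypt4gh_stream.segment import encrypt_segment

        container.seek(0)
        parsed = parse_header(container, reader)
        tail = encrypt_segment(parsed.data_keys[0], b"", data_key_rng(12))
        blob = container.getvalue() + tail
        out = io.BytesIO()
        decrypt_stream(io.BytesIO(blob), reader, out)
        assert out.getvalue() == payload

    def test_wire_size_law(self, writer, reader):
        rng = seeded_rng(11)
        writer_pair = writer
        sizes = [seeded_rng(i)(4) for i in range(10)]
        for i, raw in enumerate(sizes):
            n = int.from_bytes(raw, "little") % 200_000
            payload = generate_payload(n, seed=i)
            container = io.BytesIO()
            enc = encrypt_stream(io.BytesIO(payload), writer_pair, [reader.public_key],
                                 container, rng=rng)
            n_full, r = divmod(n, SEGMENT_SIZE)
            expected = n_full * CIPHER_SEGMENT_SIZE + ((r + SEGMENT_OVERHEAD) if r else 0)
            assert len(container.getvalue()) == enc.header_length + expected


class TestEditListPath:
    def test_cram_style_slice(self, writer, reader, rng):
        payload = generate_payload(200_000, seed=20)
        got, _, dec = roundtrip(payload, writer, reader, rng, edit_list=[950, 837])
        assert got == payload[950:1787]
        assert dec.bytes_out == 837

    def test_multi_segment_ranges_match_oracle(self, writer, reader, rng):
        payload = generate_payload(200_000, seed=21)
        lengths = [65000, 1000, 500, 70000, 3]
        got, _, _ = roundtrip(payload, writer, reader, rng, edit_list=lengths)
        assert got == naive_apply_edit_list(lengths, payload)


class TestErrors:
    def test_wrong_reader_no_access(self, writer, reader, outsider, rng):
        container = io.BytesIO()
        encrypt_stream(io.BytesIO(b"data"), writer, [reader.public_key], container, rng=rng)
        container.seek(0)
        with pytest.raises(NoAccessError):
            decrypt_stream(container, outsider, io.BytesIO())

    def test_corrupt_segment_names_ordinal(self, writer, reader, rng):
        payload = generate_payload(SEGMENT_SIZE + 10, seed=2)
        container = io.BytesIO()
        encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container, rng=rng)
        blob = bytearray(container.getvalue())
        blob[-1] ^= 0x01  # inside segment 1
        with pytest.raises(AuthenticationError, match="segment 1"):
            decrypt_stream(io.BytesIO(bytes(blob)), reader, io.BytesIO())

    def test_truncated_tail_is_loud(self, writer, reader, rng):
        container = io.BytesIO()
        encrypt_stream(io.BytesIO(b"payload"), writer, [reader.public_key], container, rng=rng)
        blob = container.getvalue()
        header_len = len(blob) - (7 + SEGMENT_OVERHEAD)
        truncated = blob[: header_len + 10]  # 10 bytes of segment only
        with pytest.raises(TruncationError):
            decrypt_stream(io.BytesIO(truncated), reader, io.BytesIO())


class TestMemoryBound:
    def test_buffered_data_bounded_during_encrypt(self, writer, reader, rng):
        # The engine may never hold more than ~4 segments: at any moment,
        # bytes pulled from the source exceed bytes pushed to the sink
        # (minus header) by at most that much.
        total = 6 * SEGMENT_SIZE + 123
        payload = generate_payload(total, seed=30)
        state = {"read": 0, "written": 0, "max_gap": 0}

        class Source:
            def __init__(self):
                self.inner = io.BytesIO(payload)

            def read(self, n):
                piece = self.inner.read(min(n, 1021))  # ragged reads
                state["read"] += len(piece)
                return piece

        class Sink:
            def write(self, data):
                state["written"] += len(data)
                state["max_gap"] = max(state["max_gap"], state["read"] - state["written"])

        encrypt_stream(Source(), writer, [reader.public_key], Sink(), rng=rng)
        assert state["max_gap"] <= 4 * SEGMENT_SIZE

    def test_decrypt_emits_progressively(self, writer, reader, rng):
        total = 5 * SEGMENT_SIZE
        payload = generate_payload(total, seed=31)
        container = io.BytesIO()
        encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container, rng=rng)
        container.seek(0)
        emitted = []

        class Sink:
            def write(self, data):
                emitted.append(len(data))

        decrypt_stream(container, reader, Sink())
        assert len(emitted) == 5  # one write per segment, not one big buffer
        assert sum(emitted) == total


class TestReencryptContainer:
    def test_data_portion_untouched_and_new_recipient_reads(self, writer, reader, outsider, rng):
        payload = generate_payload(150_000, seed=40)
        container = io.BytesIO()
        enc = encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container, rng=rng)
        container.seek(0)
        re_out = io.BytesIO()
        reencrypt_container(container, reader, [outsider.public_key], re_out)

        original = container.getvalue()
        rewritten = re_out.getvalue()
        new_header_len = len(rewritten) - (len(original) - enc.header_length)
        assert rewritten[new_header_len:] == original[enc.header_length:]

        out = io.BytesIO()
        decrypt_stream(io.BytesIO(rewritten), outsider, out)
        assert out.getvalue() == payload


def test_output_independent_of_read_granularity(writer, reader):
    payload = generate_payload(3 * SEGMENT_SIZE + 5, seed=50)
    results = []
    for granularity in (1 << 20, 333, 65536):
        rng = seeded_rng(77)

        class Source:
            def __init__(self):
                self.inner = io.BytesIO(payload)

            def read(self, n):
                return self.inner.read(min(n, granularity))

        container = io.BytesIO()
        encrypt_stream(Source(), writer, [reader.public_key], container, rng=rng)
        results.append(container.getvalue())
    assert results[0] == results[1] == results[2]
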