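"""Bounded-memory streaming encryption and decryption of whole containers.

Sources are consumed incrementally — a chunker refills a single segment
buffer regardless of the granularity the source delivers bytes in — so
peak memory stays at a small constant number of segments no matter how
large the payload is. Encryption writes the header followed by one wire
segment per 65 536-byte plaintext chunk (final chunk unpadded); decryption
re-chunks the data portion at 65 564 bytes, decrypts each segment, and
applies the per-segment edit operations when the header carries an edit
list.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from collections.abc import Callable, Iterator, Sequence

from .editlist import EditCursor, advance_cursor, apply_local_edits, validate_edit_list
from .exceptions import TruncationError
from .header import build_header, parse_header, read_header_bytes, reencrypt_header
from .keys import KeyPair
from .segment import (
    CIPHER_SEGMENT_SIZE,
    SEGMENT_OVERHEAD,
    SEGMENT_SIZE,
    decrypt_segment,
    encrypt_segment,
)

logger = logging.getLogger(__name__)

__all__ = ["StreamSummary", "rechunk", "encrypt_stream", "decrypt_stream", "reencrypt_container"]

Rng = Callable[[int], bytes]

_READ_SIZE = SEGMENT_SIZE


@dataclass(frozen=True)
class StreamSummary:
    """Accounting for one encryption or decryption run."""

    segments: int
    bytes_in: int
    bytes_out: int
    header_length: int


def _iter_source(source) -> Iterator[bytes]:
    if hasattr(source, "read"):
        while True:
            piece = source.read(_READ_SIZE)
            if not piece:
                return
            yield piece
    else:
        yield from source


def rechunk(source, size: int) -> Iterator[bytes]:
    """Losslessly resegment a byte source into chunks of exactly `size`.

    The source may be a binary file-like object or any iterable of bytes;
    its own read granularity (1-byte dribbles, giant reads, ragged pieces)
    does not affect the output. Only the final chunk may be shorter; an
    empty source yields nothing.
    """
    if size <= 0:
        raise ValueError("chunk size must be positive")
    buffer = bytearray()
    for piece in _iter_source(source):
        buffer += piece
        while len(buffer) >= size:
            yield bytes(buffer[:size])
            del buffer[:size]
    if buffer:
        yield bytes(buffer)


def encrypt_stream(
    source,
    writer: KeyPair,
    recipients: Sequence[bytes],
    sink,
    edit_list: Sequence[int] | None = None,
    rng: Rng = os.urandom,
) -> StreamSummary:
    """Encrypt a byte source into a complete container on `sink`.

    A fresh random 32-byte data key is drawn per run. The edit list, when
    given, is carried in the header for the recipients to apply at
    decryption time; the data itself is always fully encrypted.
    """
    if edit_list is not None:
        validate_edit_list(edit_list)
    data_key = rng(32)
    if len(data_key) != 32:
        raise RuntimeError("entropy source failed to deliver 32 bytes")
    header = build_header([data_key], writer, recipients, edit_list, rng)
    sink.write(header)
    segments = 0
    bytes_in = 0
    bytes_out = len(header)
    for chunk in rechunk(source, SEGMENT_SIZE):
        wire = encrypt_segment(data_key, chunk, rng(12))
        sink.write(wire)
        segments += 1
        bytes_in += len(chunk)
        bytes_out += len(wire)
        logger.debug("encrypted segment %d (%d plaintext bytes)", segments - 1, len(chunk))
    return StreamSummary(
        segments=segments,
        bytes_in=bytes_in,
        bytes_out=bytes_out,
        header_length=len(header),
    )


def decrypt_stream(
    source,
    reader: KeyPair,
    sink,
    expected_writer: bytes | None = None,
) -> StreamSummary:
    """Decrypt a container from `source`, writing recovered plaintext.

    Honors the first edit list addressed to the reader: only the kept spans
    are emitted. A trailing partial wire segment shorter than the 28-byte
    overhead is a loud truncation error, except that a final empty-plaintext
    segment (exactly 28 bytes) is accepted.
    """
    parsed = parse_header(source, reader, expected_writer)
    lengths = parsed.edit_list
    cursor = EditCursor()
    segments = 0
    bytes_in = parsed.header_length
    bytes_out = 0
    for wire in rechunk(source, CIPHER_SEGMENT_SIZE):
        if len(wire) < SEGMENT_OVERHEAD:
            raise TruncationError(
                f"container ends with a {len(wire)}-byte fragment, shorter than "
                f"the {SEGMENT_OVERHEAD}-byte segment overhead: truncated file"
            )
        plaintext = decrypt_segment(parsed.data_keys, wire, ordinal=segments)
        if lengths is None:
            kept = plaintext
        else:
            ops, cursor = advance_cursor(cursor, lengths, len(plaintext))
            kept = apply_local_edits(plaintext, ops)
        sink.write(kept)
        segments += 1
        bytes_in += len(wire)
        bytes_out += len(kept)
        logger.debug("decrypted segment %d (%d bytes kept)", segments - 1, len(kept))
    return StreamSummary(
        segments=segments,
        bytes_in=bytes_in,
        bytes_out=bytes_out,
        header_length=parsed.header_length,
    )


def reencrypt_container(
    source,
    reader: KeyPair,
    new_recipients: Sequence[bytes],
    sink,
    keep_existing: bool = False,
    rng: Rng = os.urandom,
) -> StreamSummary:
    """Re-address a container to new recipients without touching its data.

    Only the header is rebuilt; the encrypted segment stream is copied
    through byte for byte.
    """
    header = read_header_bytes(source)
    new_header = reencrypt_header(header, reader, new_recipients, keep_existing, rng)
    sink.write(new_header)
    copied = 0
    for chunk in rechunk(source, SEGMENT_SIZE):
        sink.write(chunk)
        copied += len(chunk)
    return StreamSummary(
        segments=0,
        bytes_in=len(header) + copied,
        bytes_out=len(new_header) + copied,
        header_length=len(new_header),
    )
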