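"""Edit-list algebra: partial decryption over a segmented stream.

An edit list is a flat sequence of non-negative byte counts that alternate
between *skip* and *keep*, starting with a skip, and address positions in
the decrypted plaintext. A recipient holding an edit list recovers only the
kept spans. The tail rule after the list is exhausted: a list with an odd
number of entries ends on a skip, so everything after it is kept; an even
number ends on a keep, so the remainder is discarded; the empty list keeps
everything (it is equivalent to carrying no edit list at all). That rule
lives in :func:`tail_kind` and nowhere else.

Because decryption is streamed segment by segment, the global list has to
be re-expressed as local operations against each 65 536-byte segment.
:func:`advance_cursor` does this incrementally, carrying an
:class:`EditCursor` between segments so the total plaintext length never
needs to be known up front; :func:`transform_edit_list` is the whole-file
(pure) form, defined as the fold of the incremental one.

All offsets are 0-based byte counts over plaintext; ranges are half-open.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

from .segment import SEGMENT_SIZE

__all__ = [
    "SKIP",
    "KEEP",
    "EditCursor",
    "tail_kind",
    "validate_edit_list",
    "advance_cursor",
    "transform_edit_list",
    "apply_local_edits",
    "apply_edit_list",
    "edit_list_from_ranges",
]

SKIP = "skip"
KEEP = "keep"

#: One local operation: ("skip"|"keep", byte count).
Op = tuple[str, int]


def tail_kind(lengths: Sequence[int]) -> str:
    """Implicit unbounded operation after the list is exhausted.

    A list ending on a skip (odd entry count) keeps the remainder; a list
    ending on a keep (even count) discards it. The empty list is the
    degenerate "no restriction" case and keeps everything.
    """
    if not lengths:
        return KEEP
    return KEEP if len(lengths) % 2 else SKIP


def _kind_at(index: int) -> str:
    return SKIP if index % 2 == 0 else KEEP


def validate_edit_list(lengths: Sequence[int]) -> None:
    for value in lengths:
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            raise ValueError(f"edit-list entries must be non-negative integers, got {value!r}")
        if value >= 1 << 64:
            raise ValueError("edit-list entry does not fit in 64 bits")


@dataclass(frozen=True)
class EditCursor:
    """Progress through a global edit list during streamed decryption.

    ``op_index`` points into the flat length list (indices at or past its
    end mean the implicit tail operation), ``consumed`` counts bytes already
    taken from the current entry, and ``global_offset`` counts all plaintext
    bytes seen so far.
    """

    op_index: int = 0
    consumed: int = 0
    global_offset: int = 0


def advance_cursor(
    cursor: EditCursor, lengths: Sequence[int], segment_length: int
) -> tuple[list[Op], EditCursor]:
    """Local operations for the next segment, plus the advanced cursor.

    The returned operations are canonical: adjacent same-kind runs merged,
    zero-length entries dropped, and nothing emitted after the last keep
    (bytes not covered by an operation are discarded).
    """
    if segment_length < 0 or segment_length > SEGMENT_SIZE:
        raise ValueError(f"segment length {segment_length} outside [0, {SEGMENT_SIZE}]")
    ops: list[Op] = []
    op_index, consumed = cursor.op_index, cursor.consumed
    remaining = segment_length
    while remaining > 0:
        if op_index < len(lengths):
            kind = _kind_at(op_index)
            available = lengths[op_index] - consumed
            if available <= 0:
                op_index += 1
                consumed = 0
                continue
            take = min(remaining, available)
        else:
            kind = tail_kind(lengths)
            take = remaining
        if ops and ops[-1][0] == kind:
            ops[-1] = (kind, ops[-1][1] + take)
        else:
            ops.append((kind, take))
        consumed += take
        remaining -= take
        if op_index < len(lengths) and consumed == lengths[op_index]:
            op_index += 1
            consumed = 0
    while ops and ops[-1][0] == SKIP:
        ops.pop()
    if op_index >= len(lengths):
        consumed = 0  # the implicit tail op is unbounded; no progress to track
    new_cursor = EditCursor(
        op_index=op_index,
        consumed=consumed,
        global_offset=cursor.global_offset + segment_length,
    )
    return ops, new_cursor


def transform_edit_list(
    lengths: Sequence[int], segment_lengths: Sequence[int]
) -> list[list[Op]]:
    """Split a global edit list into per-segment local operations.

    ``segment_lengths`` must describe a valid segmentation: every entry at
    most SEGMENT_SIZE and only the final one allowed to be smaller.
    """
    validate_edit_list(lengths)
    for i, seg_len in enumerate(segment_lengths):
        if not 0 <= seg_len <= SEGMENT_SIZE:
            raise ValueError(f"segment length {seg_len} outside [0, {SEGMENT_SIZE}]")
        if seg_len < SEGMENT_SIZE and i != len(segment_lengths) - 1:
            raise ValueError("only the final segment may be shorter than SEGMENT_SIZE")
    plan: list[list[Op]] = []
    cursor = EditCursor()
    for seg_len in segment_lengths:
        ops, cursor = advance_cursor(cursor, lengths, seg_len)
        plan.append(ops)
    return plan


def apply_local_edits(plaintext: bytes, ops: Sequence[Op]) -> bytes:
    """Concatenation of the kept spans of one decrypted segment."""
    kept: list[bytes] = []
    offset = 0
    for kind, length in ops:
        if kind not in (SKIP, KEEP):
            raise ValueError(f"unknown edit operation kind {kind!r}")
        if length < 0:
            raise ValueError("edit operation length must be non-negative")
        if offset + length > len(plaintext):
            raise ValueError("edit operations overrun the segment")
        if kind == KEEP:
            kept.append(plaintext[offset : offset + length])
        offset += length
    return b"".join(kept)


def apply_edit_list(lengths: Sequence[int], plaintext: bytes) -> bytes:
    """Global (non-streamed) application of an edit list to whole plaintext.

    Convenience form; the streaming path goes through advance_cursor.
    """
    validate_edit_list(lengths)
    kept: list[bytes] = []
    offset = 0
    for index, length in enumerate(lengths):
        if offset >= len(plaintext):
            break
        if _kind_at(index) == KEEP:
            kept.append(plaintext[offset : offset + length])
        offset += length
    if tail_kind(lengths) == KEEP and offset < len(plaintext):
        kept.append(plaintext[offset:])
    return b"".join(kept)


def edit_list_from_ranges(ranges: Sequence[tuple[int, int]]) -> list[int]:
    """Edit list recovering exactly the given half-open [start, end) ranges.

    Ranges must be sorted, non-overlapping and non-empty. The result has an
    even number of entries, so anything after the last range is discarded.
    """
    lengths: list[int] = []
    position = 0
    for start, end in ranges:
        if start < 0 or start >= end:
            raise ValueError(f"invalid range [{start}, {end})")
        if start < position:
            raise ValueError("ranges must be sorted and non-overlapping")
        lengths.append(start - position)
        lengths.append(end - start)
        position = end
    return lengths
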