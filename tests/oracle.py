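"""Independent reference for edit-list semantics.

Materializes the whole plaintext and walks the global skip/keep list
directly — no segmentation, no cursors — so it can arbitrate the streaming
implementation. Only the tail rule (what happens once the list is
exhausted) is imported from the package, deliberately: that rule must have
exactly one encoding, and a sign error duplicated on both sides would
otherwise cancel out.
"""

from crypt4gh_stream.editlist import KEEP, tail_kind


def naive_apply_edit_list(lengths: list[int], plaintext: bytes) -> bytes:
    kept = bytearray()
    pos = 0
    for index, span in enumerate(lengths):
        if pos >= len(plaintext):
            break
        end = min(pos + span, len(plaintext))
        if index % 2 == 1:  # odd indices are keep spans
            kept += plaintext[pos:end]
        pos = end
    else:
        if tail_kind(lengths) == KEEP:
            kept += plaintext[pos:]
    return bytes(kept)
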