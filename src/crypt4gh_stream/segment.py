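"""Inner-layer symmetric encryption of data segments.

The payload of a container is cut into plaintext segments of at most
SEGMENT_SIZE (65 536) bytes. Each segment goes on the wire as

    12-byte nonce ‖ ciphertext ‖ 16-byte MAC

under ChaCha20-IETF-Poly1305, i.e. exactly SEGMENT_OVERHEAD (28) bytes
larger than its plaintext; a full segment occupies CIPHER_SEGMENT_SIZE
(65 564) bytes. The final segment keeps its natural length and is never
padded, so the plaintext size is recoverable from the wire size.
"""

from __future__ import annotations

from collections.abc import Sequence

from ._crypto.aead import open_, seal
from .exceptions import AuthenticationError, FormatError

__all__ = [
    "SEGMENT_SIZE",
    "NONCE_SIZE",
    "MAC_SIZE",
    "SEGMENT_OVERHEAD",
    "CIPHER_SEGMENT_SIZE",
    "encrypt_segment",
    "decrypt_segment",
]

SEGMENT_SIZE = 65536
NONCE_SIZE = 12
MAC_SIZE = 16
SEGMENT_OVERHEAD = NONCE_SIZE + MAC_SIZE
CIPHER_SEGMENT_SIZE = SEGMENT_SIZE + SEGMENT_OVERHEAD


def encrypt_segment(data_key: bytes, plaintext: bytes, nonce: bytes) -> bytes:
    """Encrypt one plaintext segment; returns nonce ‖ ciphertext ‖ MAC."""
    if len(plaintext) > SEGMENT_SIZE:
        raise ValueError(
            f"segment plaintext is {len(plaintext)} bytes, limit is {SEGMENT_SIZE}"
        )
    if len(nonce) != NONCE_SIZE:
        raise ValueError("segment nonce must be 12 bytes")
    return nonce + seal(data_key, nonce, plaintext)


def decrypt_segment(
    data_keys: Sequence[bytes], segment: bytes, ordinal: int | None = None
) -> bytes:
    """Decrypt one wire segment, trying each candidate data key in order.

    Multiple keys arise from multi-key headers; the first key whose MAC
    verifies wins. Raises AuthenticationError when none does.
    """
    if len(segment) < SEGMENT_OVERHEAD:
        raise FormatError(
            f"ciphertext segment of {len(segment)} bytes is shorter than "
            f"the {SEGMENT_OVERHEAD}-byte nonce+MAC overhead"
        )
    nonce, boxed = segment[:NONCE_SIZE], segment[NONCE_SIZE:]
    for key in data_keys:
        plaintext = open_(key, nonce, boxed)
        if plaintext is not None:
            return plaintext
    where = "" if ordinal is None else f" {ordinal}"
    raise AuthenticationError(f"segment{where}: MAC verification failed for every data key")
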