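"""ChaCha20-Poly1305 AEAD (RFC 8439 §2.8), IETF construction.

`seal` returns ciphertext ‖ 16-byte tag; `open_` verifies and decrypts,
returning None on authentication failure so callers can express the
"not for me" case (multi-recipient header packets) without exceptions.
"""

from __future__ import annotations

import hmac
import struct

from .chacha20 import chacha20_block, chacha20_xor
from .poly1305 import poly1305_mac

__all__ = ["seal", "open_", "TAG_LEN"]

TAG_LEN = 16


def _tag(key: bytes, nonce: bytes, aad: bytes, ciphertext: bytes) -> bytes:
    otk = chacha20_block(key, 0, nonce)[:32]
    pad1 = b"\x00" * (-len(aad) % 16)
    pad2 = b"\x00" * (-len(ciphertext) % 16)
    mac_data = b"".join(
        (aad, pad1, ciphertext, pad2, struct.pack("<QQ", len(aad), len(ciphertext)))
    )
    return poly1305_mac(otk, mac_data)


def seal(key: bytes, nonce: bytes, plaintext: bytes, aad: bytes = b"") -> bytes:
    ciphertext = chacha20_xor(key, 1, nonce, plaintext)
    return ciphertext + _tag(key, nonce, aad, ciphertext)


def open_(key: bytes, nonce: bytes, boxed: bytes, aad: bytes = b"") -> bytes | None:
    if len(boxed) < TAG_LEN:
        raise ValueError("AEAD input shorter than the authentication tag")
    ciphertext, tag = boxed[:-TAG_LEN], boxed[-TAG_LEN:]
    if not hmac.compare_digest(tag, _tag(key, nonce, aad, ciphertext)):
        return None
    return chacha20_xor(key, 1, nonce, ciphertext)
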