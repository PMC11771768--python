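"""Poly1305 one-time authenticator (RFC 8439 §2.5).

Plain-Python Horner evaluation over 2^130 - 5; Python's arbitrary-precision
integers make the 130-bit arithmetic exact and reasonably fast (a 64 KiB
segment is 4096 multiply-reduce steps).
"""

from __future__ import annotations

__all__ = ["poly1305_mac"]

_P = (1 << 130) - 5
_CLAMP = 0x0FFFFFFC0FFFFFFC0FFFFFFC0FFFFFFF


def poly1305_mac(key: bytes, message: bytes) -> bytes:
    """16-byte tag over `message` under the 32-byte one-time `key`."""
    if len(key) != 32:
        raise ValueError("Poly1305 key must be 32 bytes")
    r = int.from_bytes(key[:16], "little") & _CLAMP
    s = int.from_bytes(key[16:], "little")
    acc = 0
    view = memoryview(message)
    for i in range(0, len(view), 16):
        block = view[i : i + 16]
        n = int.from_bytes(block, "little") | (1 << (8 * len(block)))
        acc = ((acc + n) * r) % _P
    return ((acc + s) & ((1 << 128) - 1)).to_bytes(16, "little")
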