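"""ChaCha20 stream cipher (IETF variant, 96-bit nonce / 32-bit counter).

Implements the cipher of RFC 8439 §2.4 with the block function vectorized
over the counter dimension in numpy: one call produces the keystream for a
whole data segment (up to 1024 blocks) instead of looping block by block,
which is what makes pure-Python segment encryption practical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["chacha20_block", "chacha20_xor"]

_CONSTANTS = np.array(
    [0x61707865, 0x3320646E, 0x79622D32, 0x6B206574], dtype=np.uint32
)

_KEY_LEN = 32
_NONCE_LEN = 12
_BLOCK = 64


def _keystream(key: bytes, counter: int, nonce: bytes, nblocks: int) -> np.ndarray:
    """Keystream for `nblocks` consecutive blocks, as a uint8 array."""
    if len(key) != _KEY_LEN:
        raise ValueError("ChaCha20 key must be 32 bytes")
    if len(nonce) != _NONCE_LEN:
        raise ValueError("ChaCha20 (IETF) nonce must be 12 bytes")
    state = np.empty((16, nblocks), dtype=np.uint32)
    state[0:4] = _CONSTANTS[:, None]
    state[4:12] = np.frombuffer(key, dtype="<u4").astype(np.uint32)[:, None]
    # 32-bit counter wraps per the IETF variant; segments never get close.
    state[12] = (counter + np.arange(nblocks, dtype=np.uint64)) & np.uint64(0xFFFFFFFF)
    state[13:16] = np.frombuffer(nonce, dtype="<u4").astype(np.uint32)[:, None]

    x = state.copy()
    tmp = np.empty(nblocks, dtype=np.uint32)

    def qr(a: int, b: int, c: int, d: int) -> None:
        # In-place quarter round; `tmp` holds the shifted-out rotation bits.
        xa, xb, xc, xd = x[a], x[b], x[c], x[d]
        np.add(xa, xb, out=xa)
        np.bitwise_xor(xd, xa, out=xd)
        np.left_shift(xd, 16, out=tmp)
        np.right_shift(xd, 16, out=xd)
        np.bitwise_or(xd, tmp, out=xd)
        np.add(xc, xd, out=xc)
        np.bitwise_xor(xb, xc, out=xb)
        np.left_shift(xb, 12, out=tmp)
        np.right_shift(xb, 20, out=xb)
        np.bitwise_or(xb, tmp, out=xb)
        np.add(xa, xb, out=xa)
        np.bitwise_xor(xd, xa, out=xd)
        np.left_shift(xd, 8, out=tmp)
        np.right_shift(xd, 24, out=xd)
        np.bitwise_or(xd, tmp, out=xd)
        np.add(xc, xd, out=xc)
        np.bitwise_xor(xb, xc, out=xb)
        np.left_shift(xb, 7, out=tmp)
        np.right_shift(xb, 25, out=xb)
        np.bitwise_or(xb, tmp, out=xb)

    for _ in range(10):
        qr(0, 4, 8, 12)
        qr(1, 5, 9, 13)
        qr(2, 6, 10, 14)
        qr(3, 7, 11, 15)
        qr(0, 5, 10, 15)
        qr(1, 6, 11, 12)
        qr(2, 7, 8, 13)
        qr(3, 4, 9, 14)
    x += state
    # Column b holds block b; transpose so words stream out block-major,
    # each word little-endian.
    return np.ascontiguousarray(x.T).view(np.uint8).reshape(-1)


def chacha20_block(key: bytes, counter: int, nonce: bytes) -> bytes:
    """One 64-byte block of keystream (RFC 8439 §2.3 block function)."""
    return _keystream(key, counter, nonce, 1).tobytes()


def chacha20_xor(key: bytes, counter: int, nonce: bytes, data: bytes) -> bytes:
    """Encrypt/decrypt `data` with the keystream starting at `counter`."""
    n = len(data)
    if n == 0:
        return b""
    nblocks = -(-n // _BLOCK)
    ks = _keystream(key, counter, nonce, nblocks)[:n]
    out = np.frombuffer(data, dtype=np.uint8) ^ ks
    return out.tobytes()
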