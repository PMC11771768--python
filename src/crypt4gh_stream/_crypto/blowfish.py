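"""Blowfish block cipher core, as used by the OpenBSD bcrypt KDF.

Only the pieces bcrypt needs are provided: the standard key schedule
(`expand0state`), the salted expensive schedule (`expandstate`), and raw
64-bit ECB encryption. The initial P-array and S-boxes are, by Schneier's
definition, the first 8336 hexadecimal digits of the fractional part of pi;
they are computed once at import with a Machin-formula series instead of
being inlined as an opaque 4 KiB table.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["Blowfish"]

_N_ROUNDS = 16
_MASK32 = 0xFFFFFFFF


def _atan_inv(x: int, one: int) -> int:
    """arctan(1/x) scaled by `one`, by the alternating power series."""
    total = 0
    xpow = one // x
    k = 0
    x2 = x * x
    while xpow:
        term = xpow // (2 * k + 1)
        total += term if k % 2 == 0 else -term
        xpow //= x2
        k += 1
    return total


@lru_cache(maxsize=1)
def _pi_words(nwords: int = 18 + 4 * 256) -> tuple[int, ...]:
    """First `nwords` 32-bit words of the fractional hex expansion of pi."""
    bits = nwords * 32
    one = 1 << (bits + 64)  # guard bits against series truncation
    pi = 16 * _atan_inv(5, one) - 4 * _atan_inv(239, one)  # Machin
    frac = pi - 3 * one
    words = []
    for i in range(nwords):
        shift = bits + 64 - 32 * (i + 1)
        words.append((frac >> shift) & _MASK32)
    return tuple(words)


def _stream2word(data: bytes, state: list[int]) -> int:
    """Next big-endian 32-bit word from `data`, cycling; `state` holds the cursor."""
    j = state[0]
    n = len(data)
    w = 0
    for _ in range(4):
        w = ((w << 8) | data[j]) & _MASK32
        j = (j + 1) % n
    state[0] = j
    return w


class Blowfish:
    """Mutable Blowfish state initialised to the pi-derived boxes."""

    def __init__(self) -> None:
        words = _pi_words()
        self.p = list(words[:18])
        self.s = [list(words[18 + 256 * i : 18 + 256 * (i + 1)]) for i in range(4)]

    def _f(self, x: int) -> int:
        s = self.s
        h = (s[0][x >> 24] + s[1][(x >> 16) & 0xFF]) & _MASK32
        return ((h ^ s[2][(x >> 8) & 0xFF]) + s[3][x & 0xFF]) & _MASK32

    def encipher(self, xl: int, xr: int) -> tuple[int, int]:
        p = self.p
        for i in range(_N_ROUNDS):
            xl ^= p[i]
            xr ^= self._f(xl)
            xl, xr = xr, xl
        xl, xr = xr, xl
        xr ^= p[_N_ROUNDS]
        xl ^= p[_N_ROUNDS + 1]
        return xl, xr

    def encrypt_block(self, block: bytes) -> bytes:
        xl = int.from_bytes(block[:4], "big")
        xr = int.from_bytes(block[4:8], "big")
        xl, xr = self.encipher(xl, xr)
        return xl.to_bytes(4, "big") + xr.to_bytes(4, "big")

    def expand0state(self, key: bytes) -> None:
        """Standard Blowfish key schedule (no salt)."""
        j = [0]
        for i in range(18):
            self.p[i] ^= _stream2word(key, j)
        l = r = 0
        for i in range(0, 18, 2):
            l, r = self.encipher(l, r)
            self.p[i], self.p[i + 1] = l, r
        for box in self.s:
            for i in range(0, 256, 2):
                l, r = self.encipher(l, r)
                box[i], box[i + 1] = l, r

    def expandstate(self, salt: bytes, key: bytes) -> None:
        """Expensive salted key schedule (the bcrypt 'eks' variant)."""
        j = [0]
        for i in range(18):
            self.p[i] ^= _stream2word(key, j)
        j = [0]
        l = r = 0
        for i in range(0, 18, 2):
            l ^= _stream2word(salt, j)
            r ^= _stream2word(salt, j)
            l, r = self.encipher(l, r)
            self.p[i], self.p[i + 1] = l, r
        for box in self.s:
            for i in range(0, 256, 2):
                l ^= _stream2word(salt, j)
                r ^= _stream2word(salt, j)
                l, r = self.encipher(l, r)
                box[i], box[i + 1] = l, r
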