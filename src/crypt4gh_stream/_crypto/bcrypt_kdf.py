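"""OpenBSD bcrypt_pbkdf, the KDF behind bcrypt-protected armored keys.

Each output block is a chain of `rounds` bcrypt_hash evaluations XORed
together; bcrypt_hash runs the expensive salted Blowfish schedule plus 64
plain reschedules and encrypts a fixed 32-byte magic 64 times. Output bytes
are interleaved across blocks exactly as OpenBSD does, so multi-block
requests match other implementations byte for byte.
"""

from __future__ import annotations

import hashlib

from .blowfish import Blowfish

__all__ = ["bcrypt_pbkdf"]

_MAGIC = b"OxychromaticBlowfishSwatDynamite"
_HASH_SIZE = 32


def _bcrypt_hash(sha_pass: bytes, sha_salt: bytes) -> bytes:
    state = Blowfish()
    state.expandstate(sha_salt, sha_pass)
    for _ in range(64):
        state.expand0state(sha_salt)
        state.expand0state(sha_pass)
    words = [int.from_bytes(_MAGIC[i : i + 4], "big") for i in range(0, 32, 4)]
    for _ in range(64):
        for i in range(0, 8, 2):
            words[i], words[i + 1] = state.encipher(words[i], words[i + 1])
    # OpenBSD stores the result words little-endian.
    return b"".join(w.to_bytes(4, "little") for w in words)


def bcrypt_pbkdf(password: bytes, salt: bytes, key_length: int, rounds: int) -> bytes:
    if rounds < 1:
        raise ValueError("bcrypt rounds must be >= 1")
    if not 0 < key_length <= 1024:
        raise ValueError("requested key length out of range")
    sha_pass = hashlib.sha512(password).digest()
    nblocks = -(-key_length // _HASH_SIZE)
    stride = nblocks
    amt = -(-key_length // stride)
    key = bytearray(key_length)
    remaining = key_length
    for count in range(1, nblocks + 1):
        sha_salt = hashlib.sha512(salt + count.to_bytes(4, "big")).digest()
        out = _bcrypt_hash(sha_pass, sha_salt)
        acc = bytearray(out)
        for _ in range(rounds - 1):
            sha_salt = hashlib.sha512(out).digest()
            out = _bcrypt_hash(sha_pass, sha_salt)
            for i in range(_HASH_SIZE):
                acc[i] ^= out[i]
        take = min(amt, remaining)
        for i in range(take):
            dest = i * stride + (count - 1)
            if dest >= key_length:
                break
            key[dest] = acc[i]
        remaining -= take
    return bytes(key)
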