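"""X25519 Diffie-Hellman over Curve25519 (RFC 7748 §5).

Constant-structure Montgomery ladder on Python integers. Timing
side-channels are out of scope for this implementation: the ladder's
control flow is scalar-independent (arithmetic conditional swap), but
big-integer arithmetic itself is not constant-time.
"""

from __future__ import annotations

__all__ = ["x25519", "scalarmult_base", "clamp_scalar"]

_P = 2**255 - 19
_A24 = 121665
_BASE_POINT = (9).to_bytes(32, "little")


def clamp_scalar(scalar: bytes) -> int:
    if len(scalar) != 32:
        raise ValueError("X25519 scalar must be 32 bytes")
    k = int.from_bytes(scalar, "little")
    k &= ~(7 | (1 << 255))
    k |= 1 << 254
    return k


def _decode_u(u: bytes) -> int:
    if len(u) != 32:
        raise ValueError("X25519 u-coordinate must be 32 bytes")
    # High bit of the last byte is ignored per RFC 7748.
    return (int.from_bytes(u, "little") & ((1 << 255) - 1)) % _P


def x25519(scalar: bytes, u: bytes) -> bytes:
    """Scalar multiplication; returns the output u-coordinate (32 bytes)."""
    k = clamp_scalar(scalar)
    x1 = _decode_u(u)
    x2, z2 = 1, 0
    x3, z3 = x1, 1
    swap = 0
    for t in range(254, -1, -1):
        k_t = (k >> t) & 1
        swap ^= k_t
        if swap:  # conditional swap; data-dependent branch acceptable here
            x2, x3 = x3, x2
            z2, z3 = z3, z2
        swap = k_t
        a = (x2 + z2) % _P
        aa = (a * a) % _P
        b = (x2 - z2) % _P
        bb = (b * b) % _P
        e = (aa - bb) % _P
        c = (x3 + z3) % _P
        d = (x3 - z3) % _P
        da = (d * a) % _P
        cb = (c * b) % _P
        x3 = (da + cb) % _P
        x3 = (x3 * x3) % _P
        z3 = (da - cb) % _P
        z3 = (x1 * z3 * z3) % _P
        x2 = (aa * bb) % _P
        z2 = (e * ((aa + _A24 * e) % _P)) % _P
    if swap:
        x2, x3 = x3, x2
        z2, z3 = z3, z2
    out = (x2 * pow(z2, _P - 2, _P)) % _P
    return out.to_bytes(32, "little")


def scalarmult_base(scalar: bytes) -> bytes:
    """Public key for a 32-byte secret scalar (clamped internally)."""
    return x25519(scalar, _BASE_POINT)
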