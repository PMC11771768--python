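"""Deterministic synthetic payloads and injectable randomness for tests.

Real containers wrap opaque application bytes (FASTQ, BAM, CRAM, anything);
for testing, seeded pseudorandom bytes are the representative payload —
the cipher layer is format-agnostic by design.
"""

from __future__ import annotations

import random

__all__ = ["generate_payload", "seeded_rng"]


def generate_payload(size: int, seed: int) -> bytes:
    """`size` pseudorandom bytes, a pure function of (size, seed)."""
    if size < 0:
        raise ValueError("payload size must be non-negative")
    return random.Random(seed).randbytes(size)


def seeded_rng(seed: int):
    """Deterministic drop-in for os.urandom: a callable n -> n bytes.

    For reproducible fixtures only — never a substitute for real entropy
    when producing keys that protect actual data.
    """
    state = random.Random(seed)

    def draw(n: int) -> bytes:
        return state.randbytes(n)

    return draw
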