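"""Small timing harness for encrypt/decrypt throughput.

Informational only: numbers depend entirely on the host. Each case runs a
number of warm-up passes whose timings are discarded, then `repeats` timed
passes; throughput is payload size divided by the median runtime.
"""

from __future__ import annotations

import io
import statistics
import time
from collections.abc import Callable, Sequence

from .keys import generate_keypair
from .payload import generate_payload, seeded_rng
from .stream import decrypt_stream, encrypt_stream

__all__ = ["timing_harness"]


def _timed(op: Callable[[], None], repeats: int, warmups: int, clock) -> float:
    for _ in range(warmups):
        op()
    runtimes = []
    for _ in range(repeats):
        start = clock()
        op()
        runtimes.append(clock() - start)
    return statistics.median(runtimes)


def timing_harness(
    sizes: Sequence[int],
    repeats: int = 10,
    warmups: int = 2,
    seed: int = 0,
    clock: Callable[[], float] = time.perf_counter,
) -> list[dict]:
    """Median-runtime throughput table over in-memory payloads.

    Returns one row per size with median seconds and bytes/second for both
    directions. The clock is injectable so the arithmetic is testable with
    scripted timings.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = seeded_rng(seed)
    writer = generate_keypair(rng)
    reader = generate_keypair(rng)
    rows = []
    for size in sizes:
        payload = generate_payload(size, seed)
        container = io.BytesIO()
        encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], container, rng=rng)
        wire = container.getvalue()

        def enc() -> None:
            encrypt_stream(io.BytesIO(payload), writer, [reader.public_key], io.BytesIO(), rng=rng)

        def dec() -> None:
            decrypt_stream(io.BytesIO(wire), reader, io.BytesIO())

        enc_median = _timed(enc, repeats, warmups, clock)
        dec_median = _timed(dec, repeats, warmups, clock)
        rows.append(
            {
                "size": size,
                "encrypt_median_s": enc_median,
                "encrypt_bytes_per_s": size / enc_median if enc_median > 0 else float("inf"),
                "decrypt_median_s": dec_median,
                "decrypt_bytes_per_s": size / dec_median if dec_median > 0 else float("inf"),
            }
        )
    return rows
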