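"""Seeded random-number substreams.

Every stochastic stage of the pipeline draws from its own named substream of
a single master seed, so stages can be re-run independently and the optimizer
can reuse identical Monte Carlo draws across portfolio evaluations (common
random numbers).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream is a deterministic function of ``(seed, label)`` only; the
    label is hashed with CRC-32 so the mapping is stable across sessions and
    platforms.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng([int(seed), zlib.crc32(label.encode("utf-8"))])
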