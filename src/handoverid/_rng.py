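"""Counter-based seed fan-out.

A single user-facing integer seed is combined with string/int key components
into a :class:`numpy.random.SeedSequence`, so every stage and entity of a run
draws from an independent, reproducible stream.  Keys are hashed with CRC32 so
the scheme is stable across processes and platforms (unlike ``hash()``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_for", "rng_for"]


def seed_for(seed: int, *key) -> np.random.SeedSequence:
    """Derive a SeedSequence from a base seed and an arbitrary key path."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for part in key:
        entropy.append(zlib.crc32(repr(part).encode("utf-8")))
    return np.random.SeedSequence(entropy)


def rng_for(seed: int, *key) -> np.random.Generator:
    """Independent Generator for the given key path under ``seed``."""
    return np.random.default_rng(seed_for(seed, *key))
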