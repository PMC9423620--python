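"""Deterministic RNG stream derivation.

All randomness in the package flows through numpy Generators keyed by a
user-facing integer seed plus a tuple of context keys (replicate index,
measure name, grid position, ...), so any cell of a larger experiment can be
recomputed in isolation and execution order never changes results.
"""

from __future__ import annotations

import zlib

import numpy as np


def _as_words(keys: tuple) -> list[int]:
    words = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            words.append(int(k) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode("utf-8")))
    return words


def seed_sequence(*keys) -> np.random.SeedSequence:
    """SeedSequence keyed by an arbitrary mix of ints and strings."""
    return np.random.SeedSequence(_as_words(tuple(keys)))


def generator(*keys) -> np.random.Generator:
    """A PCG64 Generator keyed by ``keys`` (ints and/or strings)."""
    return np.random.Generator(np.random.PCG64(seed_sequence(*keys)))
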