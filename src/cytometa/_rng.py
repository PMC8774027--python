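"""Deterministic random-stream derivation.

All stochastic stages take one integer seed and derive named substreams
from it, so that adding a study (or any other keyed unit) does not
perturb the draws of the units that came before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Streams for distinct key tuples are statistically independent; the
    same ``(seed, *keys)`` always yields the same stream.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return np.random.default_rng(ss)


def subseed(seed: int, *keys: int | str) -> int:
    """A 31-bit integer seed derived from ``(seed, *keys)``.

    Useful for libraries that take a plain ``random_state`` integer.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
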