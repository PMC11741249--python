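"""Seed handling.

A single user-facing seed is split into independent substreams, one per
generator, by hashing the generator's name into a ``SeedSequence`` spawn key.
Regenerating one input (say, the tissue sections) therefore does not perturb
any other stream derived from the same global seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain int."""
    rng = substream(seed, name)
    return int(rng.integers(0, 2**31 - 1))
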