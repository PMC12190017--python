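"""Deterministic seed splitting.

Every stochastic component in the package derives its generator from a single
integer seed through a named child sequence, so any sub-computation (one
nucleus field, one protocol degradation, one simulated case) is reproducible
in isolation and independent of the order in which siblings are evaluated.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(seed: int, *tags: object) -> np.random.SeedSequence:
    """SeedSequence for the child stream named by ``tags`` under ``seed``.

    Tags are hashed with CRC32 of their ``repr`` into the spawn key, which is
    stable across platforms and Python versions for ints and short strings.
    """
    key = tuple(zlib.crc32(repr(t).encode("utf8")) for t in tags)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=key)


def child_rng(seed: int, *tags: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from the named child stream."""
    return np.random.default_rng(child_seed_sequence(seed, *tags))
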