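"""Deterministic child-seed derivation.

One master seed per run; every stochastic operation derives its own
generator from (master, *tags) where tags are strings or small integers.
Strings are hashed with crc32 so the derivation is stable across processes
and platforms (Python's hash() is salted and unsuitable).
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *tags: int | str) -> np.random.SeedSequence:
    """SeedSequence for operation `tags` under `master`."""
    words = [int(master) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            words.append(zlib.crc32(t.encode("utf-8")))
        else:
            words.append(int(t) & 0xFFFFFFFF)
    return np.random.SeedSequence(words)


def child_rng(master: int, *tags: int | str) -> np.random.Generator:
    """Generator seeded from (master, *tags); identical inputs → identical streams."""
    return np.random.default_rng(child_seed(master, *tags))
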