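"""Deterministic seed derivation.

One master seed; every stochastic unit (subject, session, run, permutation
stream, voxel draw) derives its generator from the master seed plus a typed
key, so any single unit is reproducible in isolation and independent of
which other units were generated.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_ints(key: tuple) -> list[int]:
    out = []
    for k in key:
        if isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            out.append(int(k))
    return out


def seed_sequence(master_seed: int, *key) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed)] + _key_to_ints(key))


def rng_for(master_seed: int, *key) -> np.random.Generator:
    """Generator for a (master seed, typed key) pair; stable across calls."""
    return np.random.default_rng(seed_sequence(master_seed, *key))
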