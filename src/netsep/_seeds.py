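"""Deterministic sub-seed derivation.

Every stage of a run draws its randomness from a generator seeded by a
sub-seed derived from the run seed plus a stage name, so pipelines are
reproducible regardless of stage order and parallelism.
"""

from __future__ import annotations

import hashlib

import numpy as np


def subseed(seed: int, *parts: str) -> int:
    """Derive a stable 31-bit sub-seed from a run seed and stage names."""
    key = ":".join([str(int(seed)), *parts]).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, *parts: str) -> np.random.Generator:
    """A fresh ``numpy`` generator for one named stage of a run."""
    return np.random.default_rng(subseed(seed, *parts))
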