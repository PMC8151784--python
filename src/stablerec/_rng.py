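"""Seed-substream plumbing.

All randomness in the package flows from one root seed. Each stochastic
stage draws from a named substream derived via ``numpy.random.SeedSequence``
spawn keys, so stages are independent and a cohort is stable when unrelated
stages change.
"""

from __future__ import annotations

import numpy as np

# fixed stream ids — never renumber, they are part of reproducibility
STREAM_COHORT = 0
STREAM_PATIENT = 1
STREAM_SELECTION = 2
STREAM_BACKEND = 3
STREAM_SVM = 4


def substream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream identified by ``key`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def derive_int_seed(seed: int, *key: int) -> int:
    """A 31-bit integer seed for consumers that take plain ints (numba, sklearn)."""
    return int(substream(seed, *key).integers(0, 2**31 - 1))
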