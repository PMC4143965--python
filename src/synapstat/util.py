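"""Small shared helpers: unit constants and random-number plumbing."""

from __future__ import annotations

import numpy as np

#: conversion constant, defined once: 1 um^3 = 1e9 nm^3
NM3_PER_UM3 = 1.0e9

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed=None) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from one master seed.

    Every stochastic stage of a pipeline consumes its own child so that
    stages are individually reproducible and mutually independent.
    """
    return np.random.SeedSequence(master_seed).spawn(n)
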