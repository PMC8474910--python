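"""Seed fan-out.

A single top-level seed is expanded into independent per-stage streams via
``numpy.random.SeedSequence`` spawn keys, one fixed key per pipeline stage,
so each stage is reproducible on its own and adding permutations never
perturbs the simulator (or vice versa).
"""

from __future__ import annotations

import numpy as np

STAGE_TREE = 0
STAGE_PRESENCE_ABSENCE = 1
STAGE_PHENOTYPES = 2
STAGE_PERMUTATION = 3
STAGE_TREE_NULL = 4
STAGE_COVARIATES = 5


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Generator for one pipeline stage under a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))
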