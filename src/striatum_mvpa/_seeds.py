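"""Deterministic per-stage random streams.

Every stochastic stage of the pipeline draws from a stream derived from one
global seed and a fixed stage key, so a single integer reproduces the whole
experiment and stages stay independent of each other's draw counts.
"""
from __future__ import annotations

import numpy as np

# Fixed stage offsets. Never reorder or reuse a value: streams are keyed as
# SeedSequence([seed, STAGE_KEYS[stage], *extra]).
STAGE_KEYS = {
    "masks": 0,
    "betas": 1,
    "press_log": 2,
    "decode_permutations": 3,
    "rfe_permutations": 4,
    "searchlight_permutations": 5,
    "replicates": 6,
}


def stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Generator for a named pipeline stage.

    ``extra`` integers sub-key the stream (e.g. a voxel index for per-voxel
    searchlight permutations, or a replicate index).
    """
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), STAGE_KEYS[stage], *map(int, extra)])
    )
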