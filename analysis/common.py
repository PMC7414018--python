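"""Shared configuration for the numbered analysis scripts.

One phantom experiment, desk-scale: 8 subjects x 6 runs x 4 sequences on a
32 x 38 x 32 grid (2 mm voxels), decoding the three stable late runs, with
200-permutation nulls. Every script reuses this configuration so their
outputs describe a single coherent run under results/phantom_run/.
"""
from pathlib import Path

import striatum_mvpa as sm
from striatum_mvpa.decoder import DecoderConfig
from striatum_mvpa.searchlight import SearchlightConfig
from striatum_mvpa.sensitivity import RFEConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "phantom_run"


def phantom_config(seed: int = 7) -> sm.PipelineConfig:
    return sm.PipelineConfig(
        seed=seed,
        grid_shape=(32, 38, 32),
        design=sm.SyntheticDesign(n_subjects=8, n_runs=6,
                                  analysis_runs=(4, 5, 6), seed=seed),
        pattern=sm.PatternSpec(),
        decoder=DecoderConfig(n_permutations=200, seed=seed),
        rfe=RFEConfig(significance="binomial", seed=seed),
        rfe_roi="left_caudate",
        searchlight=SearchlightConfig(radius_mm=5.0, n_perm_per_voxel=10,
                                      seed=seed),
        searchlight_roi="left_caudate",
        stages=(),  # each script selects its own stage
    )
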