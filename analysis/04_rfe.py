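#!/usr/bin/env python
"""Backward voxel elimination: how few voxels sustain decoding?

Inside every leave-one-sample-out fold the least-sensitive voxel (smallest
mean squared pairwise-SVM weight) is dropped iteratively down to one voxel.
The pooled accuracy at each voxel count, with binomial-null FDR flags, shows
how sparse the discriminative pattern is; the most-selected voxels are those
surviving into each fold's final ten.
"""
import argparse
import dataclasses

import pandas as pd

import striatum_mvpa as sm
from common import RESULTS, phantom_config


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    config = dataclasses.replace(phantom_config(args.seed), stages=("rfe",))
    sm.run_pipeline(config, RESULTS)
    curve = pd.read_csv(RESULTS / "rfe_curve.tsv", sep="\t")
    sig = curve[curve["fdr_significant"]]
    print(f"ROI {config.rfe_roi}: {curve['n_voxels'].max()} voxels")
    print(f"peak accuracy {curve['accuracy'].max():.3f} at "
          f"{int(curve.loc[curve['accuracy'].idxmax(), 'n_voxels'])} voxels")
    print(f"smallest FDR-significant model: {int(sig['n_voxels'].min())} "
          "voxels" if len(sig) else "no significant voxel count")
    top = pd.read_csv(RESULTS / "rfe_top_voxels.tsv", sep="\t")
    print("most-selected voxels (grid coords):")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
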