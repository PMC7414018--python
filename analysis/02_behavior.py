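#!/usr/bin/env python
"""Score the press log and summarize accuracy and movement time.

A trial is correct when the five buttons match the target order and the
first-to-last press interval is under 2.5 s. Movement time is averaged over
correct trials only. The printed per-run means show the saturating learning
curve and the plateau over the last three runs that motivates restricting
decoding to runs 4-6.
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
    config = dataclasses.replace(phantom_config(args.seed),
                                 stages=("behavior",))
    sm.run_pipeline(config, RESULTS)
    table = pd.read_csv(RESULTS / "performance.tsv", sep="\t")
    by_run = table.groupby("run")[["accuracy", "mean_mt_s"]].mean().round(3)
    print("per-run mean performance (all subjects, all sequences):")
    print(by_run.to_string())
    late = by_run.loc[4:6, "mean_mt_s"]
    print(f"late-run movement-time spread: {late.max() - late.min():.3f} s "
          "(plateau)")


if __name__ == "__main__":
    main()
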