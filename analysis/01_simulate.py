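#!/usr/bin/env python
"""Generate the phantom experiment: masks, territory labels, press log.

Writes the four ellipsoidal nuclei, their 7-territory parcellation, the
button-press trial log and the ground-truth pattern metadata under
results/phantom_run/. The beta volumes themselves are regenerated
deterministically by the later scripts from the same seed.
"""
import argparse
import dataclasses

import striatum_mvpa as sm
from common import RESULTS, phantom_config


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    config = dataclasses.replace(phantom_config(args.seed),
                                 stages=("simulate",))
    manifest = sm.run_pipeline(config, RESULTS)
    masks = sm.generate_masks(config.grid_shape, config.voxel_size_mm,
                              config.seed)
    print(f"wrote {', '.join(manifest['outputs']['simulate'])} to {RESULTS}")
    for code, name in sm.synthdata.NUCLEUS_NAMES.items():
        print(f"  {name}: {(masks.nuclei.data == code).sum()} voxels")


if __name__ == "__main__":
    main()
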