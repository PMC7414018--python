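# striatum-mvpa

Multivoxel pattern analysis of discrete finger-sequence representations in
the human striatum, packaged as a tested, reproducible pipeline.

The scientific question: when people execute well-learned five-press finger
sequences, does the striatum (putamen and caudate nucleus) carry
sequence-specific information? Average single-voxel activity does not differ
between sequences, so the information — if present — must live in the
*distributed pattern* across voxels. This package implements the multivariate
analysis that makes that dissociation testable, for researchers working with
per-condition GLM beta images and ROI masks, plus a synthetic phantom
generator so every stage runs and is validated without any data download.

## The analysis

For each ROI, beta patterns form a samples x voxels matrix
(subjects x stable runs x K sequences; 16 x 3 x 4 = 192 samples in the
reference design). After voxelwise demeaning within each subject x run block,
a one-against-one linear SVM bank (C = 1; K(K-1)/2 = 6 classifiers for
K = 4) is evaluated under leave-one-sample-out cross-validation, predicting
each held-out sample by majority vote:

    accuracy = #correct / n,    chance = 1/K

Inference is nonparametric: the labels are randomly relabelled and the whole
cross-validation repeated (10,000 permutations at fidelity settings),

    p = (1 + #{null >= observed}) / (n_permutations + 1),

with Benjamini-Hochberg FDR (q < 0.05) across the six ROIs (left/right
putamen, caudate, and their per-hemisphere combinations). Two further
analyses characterize the representation:

* **Backward voxel elimination** — inside every fold, iteratively drop the
  voxel with the smallest mean squared classifier weight ("sensitivity")
  down to a single voxel, giving an accuracy-versus-voxel-count curve with
  FDR flags: how sparse can the pattern get while staying decodable?
* **Searchlight** — decode within a 5 mm sphere around every ROI voxel,
  test against a pooled permutation null (10 relabelled runs per voxel),
  and count the FDR-significant voxels per striatal territory
  (limbic/executive/motor/parietal/occipital/temporal parcellation).

A voxelwise repeated-measures ANOVA (sequence effect tested against the
subject x sequence interaction) provides the univariate counterpart: on data
whose class patterns are mean-balanced per voxel it stays at its nominal 5%
rate while the decoder performs far above chance — the package's central
dissociation property.

The synthetic phantom generates beta volumes as
`baseline + subject offset + run offset + pattern + noise`, where the
sequence pattern is drawn on a sparse voxel set and **exactly centered
across sequences at every voxel** — decodable multivariately, invisible
univariately, by construction. Button-press logs follow a saturating
learning curve, and trials are scored exactly as the behavioural rule
demands (correct order and movement time strictly under 2.5 s).

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and two inferential caveats of the published procedure that the
package documents and quantifies (pre-CV demeaning optimism at high
voxel-to-sample ratios, and the choice of permutation scheme).

## Worked example

The numbered scripts under `analysis/` run one coherent phantom experiment
(8 subjects x 6 runs x 4 sequences, 2 mm grid, decoding runs 4-6 with
200-permutation nulls) and write their tables under `results/phantom_run/`:

```bash
python analysis/01_simulate.py      # masks, territories, press log
python analysis/02_behavior.py     # accuracy / movement-time summaries
python analysis/03_decode_rois.py  # six-ROI decoding with permutation FDR
python analysis/04_rfe.py          # accuracy vs voxel count
python analysis/05_searchlight.py  # accuracy map + territory table
python analysis/06_report.py       # consolidated report.md
```

`03_decode_rois.py` prints (seed 7):

```
           roi  n_voxels  n_samples  chance_level  accuracy  p_permutation  fdr_significant  accuracy_foldwise_demean
  left_putamen       356         96          0.25    0.9792          0.005             True                    0.8854
 right_putamen       361         96          0.25    0.8125          0.005             True                    0.4792
  left_caudate       248         96          0.25    0.8229          0.005             True                    0.6146
 right_caudate       238         96          0.25    0.7917          0.005             True                    0.5625
 left_striatum       604         96          0.25    1.0000          0.005             True                    0.9479
right_striatum       599         96          0.25    0.9792          0.005             True                    0.6042

6/6 ROIs significant at q<0.05 (chance level 0.25)
```

Reading it: each row is one ROI's pooled leave-one-sample-out accuracy over
96 samples, its permutation p-value (floor 1/201 at 200 permutations), and
whether it survives FDR across the six ROIs. The `accuracy` column follows
the published procedure (whole-matrix demeaning), which is optimistic when
voxels outnumber samples; `accuracy_foldwise_demean` is the bias-free
variant — both far above the 25% chance level here because the phantom
plants a strong pattern (quantified in `docs/methods.md`). `02_behavior.py`
shows the movement-time plateau over runs 4-6 (1.04/1.01/1.00 s) that
motivates restricting decoding to the late runs; `04_rfe.py` reports the
sparsity of the code (on this run, decoding in left caudate stays
FDR-significant down to a 10-voxel model); `05_searchlight.py` finds 65
significant local spheres (peak accuracy 66.7%) spread over all seven
territories of the left caudate — a widespread rather than motor-confined
representation, as the whole-ROI analysis suggests.

## Layout

```
src/striatum_mvpa/   synthdata, behavior, assembly, decoder, sensitivity,
                     searchlight, univariate, pipeline (+ seeding, svm core)
analysis/            numbered drivers for the phantom experiment
tests/               pytest suite, including end-to-end scientific checks
scripts/acceptance.py
docs/methods.md      models, defaults, caveats, problem sizes
```
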