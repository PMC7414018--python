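# Methods

This note documents the models, procedures and numerical choices behind the
package: what the decoding pipeline computes, what the synthetic phantom
emulates (and deliberately does not), which defaults matter and why, and the
known limitations a user should weigh before trusting a number.

## The decoding model

The unit of analysis is a beta pattern: one value per voxel per
(subject, run, sequence) cell, the GLM amplitude estimate for correct
executions of that finger sequence in that run. For a given ROI the pipeline
assembles a samples x voxels matrix with one row per cell — with 16 subjects,
3 analysis runs and 4 sequences, 192 rows — and asks whether the sequence
label is decodable from the joint pattern.

**Demeaning.** Before any training, each subject x run block (the K rows of
one run) has its voxelwise mean across sequences subtracted. This removes
block-level offsets (scanner/session effects, run-level activation level)
exactly. It is applied once to the full matrix, as in the published
procedure; see *Inferential caveats* below for the consequence.

**Classifier.** One soft-margin linear SVM per unordered pair of sequences
(K=4 gives 6), penalty C = 1 (the libsvm default), each trained only on its
pair's rows. A sample is classified by evaluating all pairwise decision
functions and taking the class with the most votes; vote ties go to the
lowest class label by default (a fixed, documented rule; a
largest-summed-decision-value rule is available as
`vote_tie_rule="decision_sum"`).

**Cross-validation.** Leave-one-sample-out (LOSO): each of the n rows is
held out once, the 6 models are trained on the remaining n-1 rows, and the
pooled fraction of correctly predicted held-out rows is the ROI's accuracy.
Internally LOSO is decomposed per pair — the pair (i, j) model is identical
for every fold whose held-out sample is in neither class, so each pair needs
one full fit plus one leave-one-out fit per pair member, computed on
precomputed Gram matrices through scikit-learn's libsvm binding. The test
suite asserts this is prediction-for-prediction identical to the naive
per-fold procedure and to the public `sklearn.svm.SVC` on weights, decision
values and predictions.

**Inference.** The null distribution is built by relabelling the samples and
rerunning the *entire* LOSO procedure per permutation; the p-value is
(1 + #{null >= observed}) / (n_permutations + 1), never zero. Two
relabelling schemes exist:

* `global` (default): one random permutation of the full label vector —
  the literal published description;
* `within_run`: labels permuted within each subject x run block, which
  preserves the one-sample-per-class-per-block structure of the design and
  is the exactly exchangeable null for it.

Across the six ROIs (left/right putamen, caudate, and the per-hemisphere
combinations) p-values are corrected with Benjamini-Hochberg FDR at
q = 0.05, within one run-selection x class-selection analysis family.
The fidelity default is 10,000 permutations; the pipeline default is 500,
which resolves p down to 1/501 — ample for q < 0.05 across six tests.

**Sensitivity and backward elimination.** A voxel's sensitivity is the mean
of its squared weights across the 6 pairwise models. The sparsity analysis
repeats, inside every LOSO fold: train on the remaining voxels, record the
held-out prediction, drop the least-sensitive voxel (ties to the lowest
voxel index), down to one voxel. Pooling predictions at each voxel count m
gives an accuracy curve over m = V..1. Per-m significance uses a binomial
null Bin(n, 1/K) by default, FDR-corrected across voxel counts; a
permutation variant that reruns the whole elimination per relabelling is
implemented and tested, but costs n_permutations x n_folds x n_voxels SVM
fits and is reserved for small problems. "Most-selected" voxels are those
most often surviving into a fold's final `survival_depth` (default 10)
voxel set.

**Searchlight.** Every in-ROI voxel centres a sphere of radius 5 mm
(centre-to-centre distance <= radius, so on the 2 mm grid a deep-interior
sphere holds exactly 81 voxels); spheres are intersected with the ROI.
Sphere-restricted LOSO accuracy is assigned to the centre. The null pools
`n_perm_per_voxel` (default 10) relabelled searchlight runs per voxel —
independent streams seeded by voxel index — into one distribution; per-voxel
p-values against the pool are FDR-corrected and the smallest surviving
accuracy is reported as the map threshold. Because demeaning is voxelwise,
demeaning the whole ROI once and extracting spheres afterwards equals
per-sphere demeaning; a test asserts this rather than assuming it.
Significant voxels are tallied per territory within each nucleus (N and
percent of that nucleus's significant voxels).

**Univariate check.** The multivariate claim is paired with a voxelwise
repeated-measures ANOVA: each subject's values are averaged over runs and
the sequence effect is tested against the subject x sequence interaction
(F with (K-1, (S-1)(K-1)) df). This is the exact test under the phantom's
compound-symmetric covariance. A one-way ANOVA on block-demeaned values was
rejected during design: block-centering removes degrees of freedom the
one-way test still assumes, inflating its size to ~12% in simulation, and a
subject x run blocked two-way ANOVA inflates to ~28% at informative voxels
because subject-specific patterns repeat across runs; the rm-ANOVA form is
exact (5.0-5.2% empirical size at nominal 5%, 20,000-voxel simulations) for
both noise and informative voxels.

## The synthetic phantom

The generator emulates the *statistical* structure the analysis needs, not
fMRI physics:

    beta(s, r, c, v) = baseline(v) + a_s + b_{s,r} + P_{s,c,v} + noise

* `baseline(v)`: a smooth Gaussian random field (amplitude 1), shared by all
  volumes — a stand-in for mean task activation.
* `a_s ~ N(0, 0.5^2)`, `b_{s,r} ~ N(0, 0.25^2)`: scalar subject and run
  offsets. Scalar by design: the demeaning stage removes them exactly, which
  makes demeaning itself testable against an offset-free twin dataset.
* `P`: the sequence pattern, nonzero only on `n_informative_voxels`
  (default 240) voxels drawn from the striatal mask (or planted at a
  requested site). Per subject it mixes a shared and an idiosyncratic
  component, `P_s = w P_shared + (1-w) P_subject`, all components drawn
  N(0, tau^2), then **re-centered across classes at every voxel**, so the
  per-voxel univariate class effect is exactly zero by construction — not
  just in expectation. This is the property that makes sequences decodable
  multivariately yet invisible univariately.
* `noise ~ N(0, 1)` i.i.d. per voxel and volume; optional Gaussian smoothing
  (FWHM in mm) is applied to the noise field only, so the exact mean balance
  of P survives. Smoothing is not variance-renormalized; smoothed phantoms
  have proportionally quieter voxels.
* Masks: four disjoint ellipsoids (putamen lateral and ventral, caudate
  medial and dorsal) scaled to the grid, each cut into 7 territories by
  four long-axis slabs with dorsoventral splits — a reproducible geometric
  stand-in for a connectivity parcellation, sufficient to test territory
  quantification. The seed jitters nucleus centres by up to half a voxel.

**Subject consistency defaults to 0** (fully idiosyncratic patterns). Any
shared component w > 0 creates a *true* per-voxel univariate class effect of
order w*tau (the shared pattern is centered across classes, not zero per
class), which would contradict the univariate-null construction at realistic
amplitudes; and fine-grained voxel patterns are in practice poorly aligned
across subjects after anatomical normalization. Pooled LOSO decoding still
works at w = 0 because every held-out sample's subject contributes its other
K x runs - 1 samples to training; the run-to-run reliability of the
subject's own pattern carries the classification.

**Pattern amplitude default: tau = 1.1.** No effect-size estimate exists
for striatal sequence patterns at this granularity, so tau was
calibrated once so that whole-ROI accuracy on the default 16-subject design,
measured with *within-training-fold* demeaning (the bias-free variant, see
below), lands in the upper-30s/low-40s percent range typical of this kind of
between-sequence striatal decoding. It is a synthetic stand-in, not an
estimate of the real effect size.

**Behaviour.** Press logs follow a saturating learning curve
`MT_r = MT_inf + (MT_0 - MT_inf) exp(-r / tau_learn)` (defaults 2.0 s ->
1.0 s, tau_learn = 1.5 runs) with lognormal trial jitter (sd 0.12); per-run
error probability decays along the same curve (0.30 -> 0.07). Sequence 1,
the simple ascending sequence, is faster by 0.15 s and half as error-prone,
mirroring the regular sequence's behavioural advantage. Error trials carry a
non-identity permutation of the target order. 12 executions per sequence per
run (4 trial blocks x 3 repetitions).

What the phantom does **not** model: HRF convolution and temporal noise
(betas are emitted directly), spatially correlated or non-Gaussian noise,
physiological artefacts, head motion, inter-subject anatomical variability,
or any topographic organisation of the pattern. Passing tests therefore
certify the *pipeline machinery and its statistical calibration under the
stated assumptions*, not properties of real striatal data.

## Inferential caveats found and documented during development

**Pre-CV demeaning is anticonservative when voxels are plentiful.** Because
each block's class mean is subtracted using *all* samples, the held-out
sample equals the negative sum of its block partners, which remain in the
training set. On signal-free phantoms this inflates LOSO accuracy above
chance — ~41% (chance 25%) at 200 voxels x 192 samples, ~67% at ~700 voxels —
while leaving it untouched when voxels are few relative to samples. This is
a property of the published procedure, which the package reproduces
deliberately.

* Under the `global` permutation scheme the null does *not* inherit this
  optimism (random relabelling destroys the one-sample-per-class-per-block
  alignment; the null mean stays at chance), so global-null p-values on
  signal-free data are anticonservative at high voxel-to-sample ratios
  (8-28% empirical size at nominal 5% in our simulations).
* Under the `within_run` scheme the null preserves the block structure and
  is exactly exchangeable with the observed statistic; its p-values are
  valid at any voxel count (2-5% empirical size, uniform p-values).

The package keeps `global` as the default for fidelity to the published
description and reports chance-level null means with it; calibration-
sensitive analyses should use `permutation_scheme="within_run"` or
`within_fold_demean=True` (which recomputes block means from training rows
only and removes the bias at the source, at the cost of the naive
per-fold training path). The test suite checks type-I control and p-value
uniformity under the exchangeable scheme, and chance-level null means under
the default scheme.

**Whole-pipeline accuracies on the default phantom** consequently sit above
the tau-driven signal level (the demeaning optimism and the signal add);
they are internally consistent and permutation-calibrated per scheme as
described, but their absolute values should not be read as realistic
decoding accuracies.

## Numerical and design choices

* Voxel columns are ordered by ascending linear index with x fastest,
  `x + nx (y + ny z)`, so weight vectors map back onto the grid
  deterministically; combined ROIs concatenate per-code column blocks.
* Grid agreement between volumes is checked with an affine tolerance of
  1e-4 (NIfTI header float jitter).
* Sensitivity ties in backward elimination, and vote ties under the default
  rule, break towards the lowest index/label — determinism over elegance.
* All randomness derives from one global seed via fixed per-stage keys
  (`_seeds.STAGE_KEYS`); per-voxel searchlight permutations sub-key by voxel
  index so pooling stays valid and any voxel's null is reproducible in
  isolation.
* Movement-time threshold is strict (< 2.5 s); trials with a wrong number
  of presses count as incorrect rather than being dropped, keeping the
  accuracy denominator at the number of trials. Which runs count as
  "stable" is configuration (default runs 4-6), not an inference the
  package makes.
* For the 3-class re-analysis (excluding the simple sequence) demeaning
  uses the included classes only by default; demeaning over all four before
  subsetting is available by ordering the operations differently.
* Empty-ROI, incomplete-block, missing-volume and grid-mismatch conditions
  raise errors naming the offender; degenerate (all-identical) class pairs
  are refused rather than silently fitted.

## Problem sizes used by the shipped tests and analyses

Desk-scale sizes keep the full suite within minutes while preserving every
structural property: chance-level null means are verified at the full
192-sample, 200-voxel, 500-permutation scale; type-I control and p-value
uniformity on 100 signal-free replicates (48 samples, 10 voxels, 200
permutations each, exchangeable scheme); the dissociation property on a
16-subject phantom with ~250-700-voxel ROIs and 100 permutations; sparse
recovery with 5 informative voxels in a 30-voxel ROI (96 samples); and
searchlight localization/FDR on 120- and 40-voxel ROIs. The analysis
scripts run an 8-subject phantom on a 32 x 38 x 32 grid with 200-permutation
nulls. All sizes are stated in the scripts and tests themselves.

## Known limitations

* The libsvm binding is called below the estimator API for speed; the
  public-API equivalence is pinned by tests against the installed
  scikit-learn.
* The permutation variant of per-voxel-count RFE significance is exact but
  computationally heavy; the binomial default ignores the dependence
  between folds (each sample is predicted once, so the binomial n is the
  sample count, but folds share training data), which makes it mildly
  anticonservative for accuracies near chance.
* The pooled searchlight null assumes sphere nulls are comparable across
  voxels; sphere size varies at ROI boundaries, so boundary voxels are
  tested against a slightly mismatched null — the published procedure
  shares this property.
* Territory sectors are geometric stand-ins; percentages in the territory
  table are meaningful for pipeline testing, not neuroanatomy.
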