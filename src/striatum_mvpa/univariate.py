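"""Voxelwise univariate check for mean activity differences between classes.

The multivariate result is only interesting if single voxels carry no class
information on average, so the pipeline ships the univariate counterpart:
a per-voxel repeated-measures ANOVA. Each subject's beta values are averaged
over runs, giving one subject x class table per voxel, and the class effect
is tested against the subject x class interaction — the standard
one-within-factor rm-ANOVA F with (K-1, (S-1)(K-1)) degrees of freedom.

Under the synthetic generator's structure (class patterns exactly centered
across classes within subject, i.i.d. Gaussian noise) this test is exact at
its nominal level at every voxel, informative or not, while a shared
across-subject pattern would be detected. Naive one-way ANOVA on
block-demeaned data is anticonservative here (the block centering removes
degrees of freedom the one-way test still assumes), which is why the
repeated-measures form is used.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .assembly import SampleMatrix


def sequence_anova(samples: SampleMatrix) -> np.ndarray:
    """Per-voxel rm-ANOVA p-value for a class effect. Vectorized over voxels.

    Requires every subject to have every class in every run (the standard
    balanced design the assembly stage produces).
    """
    subjects = np.unique(samples.subjects)
    classes = np.unique(samples.labels)
    S, K, V = len(subjects), len(classes), samples.n_voxels
    if S < 2 or K < 2:
        raise ValueError("need at least 2 subjects and 2 classes")
    # run-averaged subject x class x voxel table
    y = np.empty((S, K, V))
    for si, s in enumerate(subjects):
        for ci, c in enumerate(classes):
            sel = (samples.subjects == s) & (samples.labels == c)
            if not sel.any():
                raise ValueError(f"subject {s} has no samples of class {c}")
            y[si, ci] = samples.values[sel].mean(axis=0)
    grand = y.mean(axis=(0, 1))
    subj_mean = y.mean(axis=1)          # (S, V)
    class_mean = y.mean(axis=0)         # (K, V)
    ss_class = S * ((class_mean - grand) ** 2).sum(axis=0)
    ss_subj = K * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_error = ss_total - ss_class - ss_subj
    df1, df2 = K - 1, (S - 1) * (K - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_class / df1) / (ss_error / df2)
    return stats.f.sf(F, df1, df2)
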