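"""Classifier weight maps, voxel sensitivity, and backward voxel elimination.

A voxel's sensitivity is the mean of its squared linear-SVM weights across
the pairwise classifiers. The backward-elimination (sparsity) analysis asks
how few voxels sustain significant decoding: inside every leave-one-sample-
out fold the pairwise models are trained on the remaining voxels, the least
sensitive voxel is dropped, and the loop repeats until a single voxel is
left; pooling the held-out predictions at each voxel count m yields an
accuracy curve over m = n_voxels .. 1.

Per-m significance is assessed against a binomial null by default; a
permutation null (rerunning the entire elimination on relabelled data) is
available and exercised in tests, but its cost grows as
n_permutations x n_folds x n_voxels SVM fits, which is only reasonable for
small problems. Either way the curve is corrected across voxel counts with
Benjamini-Hochberg FDR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import _svm
from ._seeds import stage_rng
from .assembly import SampleMatrix, values_to_volume
from .decoder import (DecoderConfig, PairwiseClassifierSet, _as_xy,
                      _check_classes, _tally, fdr_correct, train_pairwise)


@dataclass
class RFEConfig:
    significance: str = "binomial"      # or "permutation"
    n_permutations: int = 500           # used by the permutation null
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.significance not in ("binomial", "permutation", "none"):
            raise ValueError(f"unknown significance {self.significance!r}")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class EliminationTrace:
    """Result of the cross-validated backward voxel elimination."""

    classes: np.ndarray
    n_samples: int
    # order[f, t]: original voxel index eliminated at step t of fold f; the
    # last entry of each row is the lone survivor.
    elimination_order: np.ndarray
    accuracies: np.ndarray              # accuracies[m - 1] = accuracy with m voxels
    p_values: np.ndarray | None = None
    fdr_significant: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.elimination_order.shape[1]

    @property
    def n_folds(self) -> int:
        return self.elimination_order.shape[0]

    def accuracy_at(self, m: int) -> float:
        return float(self.accuracies[m - 1])

    def selection_scores(self, survival_depth: int = 10) -> np.ndarray:
        """Per voxel: folds in which it survived into the last-d voxel set."""
        V = self.n_voxels
        d = min(survival_depth, V)
        last = self.elimination_order[:, V - d:]
        scores = np.zeros(V, dtype=np.int64)
        idx, counts = np.unique(last, return_counts=True)
        scores[idx] = counts
        return scores

    def to_frame(self) -> pd.DataFrame:
        ms = np.arange(1, self.n_voxels + 1)
        df = pd.DataFrame({"n_voxels": ms, "accuracy": self.accuracies})
        if self.p_values is not None:
            df["p"] = self.p_values
            df["fdr_significant"] = self.fdr_significant
        return df.iloc[::-1].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sensitivity


def compute_sensitivity(models: PairwiseClassifierSet) -> np.ndarray:
    """s(v) = mean over class pairs of the squared weight at voxel v."""
    if models.n_pairs < 1:
        raise ValueError("need at least one pairwise model")
    return np.mean(models.weights ** 2, axis=0)


def full_data_weight_maps(samples: SampleMatrix,
                          config: DecoderConfig | None = None) -> dict:
    """Pairwise weight volumes from models trained on *all* samples.

    Returns ``{(i, j): 3D volume}`` plus the mean-sensitivity volume under
    the key ``"sensitivity"``; voxels outside the ROI are zero.
    """
    config = config or DecoderConfig()
    models = train_pairwise(samples.values, samples.labels, config.cost)
    out = {}
    for a, pair in enumerate(models.pairs):
        out[pair] = values_to_volume(models.weights[a], samples.voxel_coords,
                                     samples.grid_shape)
    out["sensitivity"] = values_to_volume(
        compute_sensitivity(models), samples.voxel_coords, samples.grid_shape)
    return out


# ---------------------------------------------------------------------------
# backward elimination


def _elimination_core(X, y, classes, cost, tie_rule,
                      keep_orders: bool = True):
    """One full backward elimination; returns (orders, accuracies).

    Per LOSO fold: train pairwise models on the active voxels of the
    training rows, record the held-out decision values, drop the least
    sensitive voxel (ties -> lowest voxel index), repeat down to one voxel.
    Gram matrices are downdated by the dropped voxel's outer product, so
    each step costs one small SVM fit per pair.
    """
    n, V = X.shape
    pairs = list(combinations(classes.tolist(), 2))
    n_pairs = len(pairs)
    dec = np.empty((n, V, n_pairs))  # [fold, m-1, pair]
    orders = np.empty((n, V), dtype=np.int64) if keep_orders else None

    for k in range(n):
        tr = np.arange(n) != k
        ytr = y[tr]
        Xtr_full = X[tr]
        xk = X[k]
        # per-pair training rows (class i block first), gram, test vector
        pair_rows, grams, gtests, ypairs = [], [], [], []
        for (i, j) in pairs:
            pi = np.concatenate([np.flatnonzero(ytr == i),
                                 np.flatnonzero(ytr == j)])
            Xp = Xtr_full[pi]
            pair_rows.append(Xp)
            grams.append(Xp @ Xp.T)
            gtests.append(Xp @ xk)
            ypairs.append(ytr[pi].astype(np.float64))
        active = np.arange(V)
        for step in range(V):
            m = V - step
            sens = np.zeros(len(active))
            for a in range(n_pairs):
                model = _svm.fit_gram(grams[a], ypairs[a], cost)
                d = float(np.dot(model[3][0], gtests[a][model[0]])
                          + model[4][0])
                dec[k, m - 1, a] = d
                w = model[3][0] @ pair_rows[a][model[0]][:, active]
                sens += w * w
            if m == 1:
                if keep_orders:
                    orders[k, V - 1] = active[0]
                break
            drop_rel = int(np.argmin(sens))    # first min -> lowest index
            v = active[drop_rel]
            if keep_orders:
                orders[k, step] = v
            for a in range(n_pairs):
                col = pair_rows[a][:, v]
                grams[a] -= np.outer(col, col)
                gtests[a] -= col * xk[v]
            active = np.delete(active, drop_rel)

    accuracies = np.empty(V)
    for m in range(1, V + 1):
        preds = _tally(dec[:, m - 1, :], classes, pairs, tie_rule)
        accuracies[m - 1] = (preds == y).mean()
    return orders, accuracies


def backward_elimination(samples, config: DecoderConfig | None = None,
                         rfe: RFEConfig | None = None) -> EliminationTrace:
    """Cross-validated recursive voxel elimination with per-m significance."""
    config = config or DecoderConfig()
    rfe = rfe or RFEConfig()
    X, y, _ = _as_xy(samples)
    if X.shape[1] < 1:
        raise ValueError("empty ROI")
    classes = _check_classes(y, min_per_class=2)
    orders, acc = _elimination_core(X, y, classes, config.cost,
                                    config.vote_tie_rule)
    trace = EliminationTrace(classes, len(y), orders, acc)
    if rfe.significance == "none":
        return trace
    n, K = len(y), len(classes)
    if rfe.significance == "binomial":
        correct = np.rint(acc * n).astype(int)
        trace.p_values = stats.binom.sf(correct - 1, n, 1.0 / K)
    else:
        rng = stage_rng(rfe.seed, "rfe_permutations")
        null = np.empty((rfe.n_permutations, X.shape[1]))
        for b in range(rfe.n_permutations):
            yp = rng.permutation(y)
            _, null[b] = _elimination_core(X, yp, classes, config.cost,
                                           config.vote_tie_rule,
                                           keep_orders=False)
        trace.p_values = (1.0 + (null >= acc[None, :]).sum(axis=0)) / (
            rfe.n_permutations + 1.0)
    trace.fdr_significant = fdr_correct(trace.p_values, rfe.fdr_q)
    return trace


def top_selected_voxels(trace: EliminationTrace, k: int = 10,
                        survival_depth: int = 10) -> pd.DataFrame:
    """Voxels most often surviving into each fold's final-`survival_depth` set.

    Ties are broken towards the lower voxel index. Returns at most k rows
    (with a warning if k exceeds the number of voxels).
    """
    if k > trace.n_voxels:
        warnings.warn(f"k={k} exceeds {trace.n_voxels} voxels; truncating")
        k = trace.n_voxels
    scores = trace.selection_scores(survival_depth)
    order = np.lexsort((np.arange(len(scores)), -scores))[:k]
    return pd.DataFrame({"voxel": order, "selection_count": scores[order]})
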