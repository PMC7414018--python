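"""Searchlight decoding over ROI voxels with a pooled permutation null.

Every in-ROI voxel becomes the centre of a sphere (default radius 5 mm,
centre-to-centre distance <= radius, intersected with the ROI); the
one-against-one LOSO decoder runs on the sphere's voxel columns and the
accuracy is assigned to the centre. The null pools a small number of
label-permutation runs per voxel (default 10) across all voxels into one
distribution; per-voxel p-values against the pool are FDR-corrected, and the
smallest accuracy that survives is reported as the map threshold.
Significant voxels are finally counted per atlas territory within each
nucleus.

Demeaning happens once on the whole-ROI matrix before sphere extraction;
because demeaning is voxelwise this is identical to demeaning per sphere
(asserted by a test, not assumed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .assembly import MaskVolume, SampleMatrix
from .decoder import (DecoderConfig, _check_classes, _loso_predict,
                      fdr_correct, permutation_null_accuracies)


@dataclass
class SearchlightConfig:
    radius_mm: float = 5.0
    n_perm_per_voxel: int = 10
    fdr_q: float = 0.05
    seed: int = 0
    # Relabelling scheme for the pooled null. The block-exchangeable scheme
    # is the default here: sphere voxel counts rival the sample count, where
    # the whole-matrix demeaning optimism is large, and only the within-block
    # null inherits that optimism and stays calibrated (see methods note).
    permutation_scheme: str = "within_run"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.n_perm_per_voxel < 1:
            raise ValueError("need at least one permutation per voxel")
        if self.permutation_scheme not in ("global", "within_run"):
            raise ValueError(
                f"unknown permutation scheme {self.permutation_scheme!r}")


@dataclass
class SearchlightMap:
    accuracies: np.ndarray        # per in-ROI voxel (column order)
    sphere_sizes: np.ndarray
    voxel_coords: np.ndarray
    grid_shape: tuple
    affine: np.ndarray
    voxel_size_mm: float

    def to_volume(self, fill=np.nan) -> np.ndarray:
        vol = np.full(self.grid_shape, fill, dtype=np.float64)
        vol[tuple(self.voxel_coords.T)] = self.accuracies
        return vol


@dataclass
class PooledNullResult:
    map: SearchlightMap
    null_accuracies: np.ndarray   # pooled, size n_voxels * n_perm_per_voxel
    p_values: np.ndarray
    significant: np.ndarray
    accuracy_threshold: float     # min accuracy surviving FDR (nan if none)


# ---------------------------------------------------------------------------
# sphere geometry


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centre-to-centre distance is <= radius."""
    reach = int(np.floor(radius_mm / voxel_size_mm))
    axes = np.arange(-reach, reach + 1)
    dx, dy, dz = np.meshgrid(axes, axes, axes, indexing="ij")
    keep = (dx ** 2 + dy ** 2 + dz ** 2) * voxel_size_mm ** 2 <= radius_mm ** 2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_indices(center, mask: MaskVolume, radius_mm: float,
                   voxel_size_mm: float | None = None) -> np.ndarray:
    """In-mask voxel coordinates within ``radius_mm`` of the centre voxel."""
    center = np.asarray(center)
    vs = voxel_size_mm or mask.voxel_size_mm
    maskb = mask.binary()
    if not maskb[tuple(center)]:
        raise ValueError(f"sphere centre {tuple(center)} is outside the mask")
    pts = center + sphere_offsets(radius_mm, vs)
    shape = np.asarray(mask.grid_shape)
    inside = ((pts >= 0) & (pts < shape)).all(axis=1)
    pts = pts[inside]
    return pts[maskb[tuple(pts.T)]]


def _column_lookup(samples: SampleMatrix) -> np.ndarray:
    """Volume mapping grid voxel -> sample-matrix column (-1 outside ROI)."""
    lut = np.full(samples.grid_shape, -1, dtype=np.int64)
    lut[tuple(samples.voxel_coords.T)] = np.arange(samples.n_voxels)
    return lut


def _sphere_columns(samples: SampleMatrix, config: SearchlightConfig):
    lut = _column_lookup(samples)
    offsets = sphere_offsets(config.radius_mm, samples.voxel_size_mm)
    shape = np.asarray(samples.grid_shape)
    for v in range(samples.n_voxels):
        pts = samples.voxel_coords[v] + offsets
        inside = ((pts >= 0) & (pts < shape)).all(axis=1)
        cols = lut[tuple(pts[inside].T)]
        yield v, np.sort(cols[cols >= 0])


# ---------------------------------------------------------------------------
# searchlight decoding


def searchlight_map(samples: SampleMatrix, config: SearchlightConfig | None = None,
                    decoder_config: DecoderConfig | None = None,
                    ) -> SearchlightMap:
    """LOSO decoding accuracy in a sphere around every in-ROI voxel."""
    config = config or SearchlightConfig()
    decoder_config = decoder_config or DecoderConfig()
    _check_classes(samples.labels, min_per_class=2)
    acc = np.empty(samples.n_voxels)
    sizes = np.empty(samples.n_voxels, dtype=np.int64)
    for v, cols in _sphere_columns(samples, config):
        Xs = samples.values[:, cols]
        preds = _loso_predict(Xs, samples.labels, decoder_config.cost,
                              decoder_config.vote_tie_rule)
        acc[v] = (preds == samples.labels).mean()
        sizes[v] = len(cols)
    return SearchlightMap(acc, sizes, samples.voxel_coords.copy(),
                          samples.grid_shape, samples.affine.copy(),
                          samples.voxel_size_mm)


def pooled_permutation_threshold(samples: SampleMatrix,
                                 config: SearchlightConfig | None = None,
                                 decoder_config: DecoderConfig | None = None,
                                 ) -> PooledNullResult:
    """Pooled permutation null, per-voxel p-values, FDR mask and threshold.

    Per voxel, ``n_perm_per_voxel`` label permutations (independent streams
    seeded by voxel index) rerun the sphere's LOSO decoding; all null
    accuracies are pooled. p(v) = (1 + #{pool >= acc_v}) / (n_pool + 1).
    """
    config = config or SearchlightConfig()
    decoder_config = decoder_config or DecoderConfig()
    smap = searchlight_map(samples, config, decoder_config)
    y = samples.labels
    blocks = (samples.subjects.astype(np.int64) * 1_000_003 + samples.runs
              if config.permutation_scheme == "within_run" else None)
    nulls = []
    for v, cols in _sphere_columns(samples, config):
        rng = stage_rng(config.seed, "searchlight_permutations", v)
        Xs = samples.values[:, cols]
        nulls.append(permutation_null_accuracies(
            Xs, y, decoder_config.cost, config.n_perm_per_voxel, rng,
            decoder_config.vote_tie_rule, config.permutation_scheme, blocks))
    pool = np.sort(np.concatenate(nulls))
    # p = (1 + #{pool >= acc}) / (n + 1), via right-tail rank in sorted pool
    ranks = np.searchsorted(pool, smap.accuracies, side="left")
    p = (1.0 + (pool.size - ranks)) / (pool.size + 1.0)
    significant = fdr_correct(p, config.fdr_q)
    threshold = float(smap.accuracies[significant].min()) if significant.any() \
        else float("nan")
    return PooledNullResult(smap, pool, p, significant, threshold)


# ---------------------------------------------------------------------------
# atlas quantification


def quantify_by_atlas(significant_volume: np.ndarray, nuclei: MaskVolume,
                      territories: MaskVolume) -> pd.DataFrame:
    """Count significant voxels per territory within each nucleus.

    Returns one row per (nucleus, territory) with the count N and the
    percentage of that nucleus's significant voxels. Significant voxels
    with no territory label are tallied under ``"unlabeled"`` with a
    warning. Percentages within a nucleus sum to 100 (all-zero when the
    nucleus has no significant voxels).
    """
    sig = np.asarray(significant_volume, dtype=bool)
    if sig.shape != nuclei.grid_shape:
        raise ValueError("significance volume and nuclei grids differ")
    rows = []
    territory_codes = sorted(territories.labels) or sorted(
        int(c) for c in np.unique(territories.data) if c != 0)
    for ncode in sorted(c for c in np.unique(nuclei.data) if c != 0):
        in_nucleus = nuclei.data == ncode
        nsig = sig & in_nucleus
        total = int(nsig.sum())
        nname = nuclei.labels.get(int(ncode), f"nucleus_{ncode}")
        unlabeled = int((nsig & (territories.data == 0)).sum())
        if unlabeled:
            warnings.warn(f"{unlabeled} significant voxels in {nname} have "
                          "no territory label")
        for tcode in territory_codes:
            n = int((nsig & (territories.data == tcode)).sum())
            rows.append({
                "nucleus": nname, "territory":
                territories.labels.get(int(tcode), f"territory_{tcode}"),
                "n_significant": n,
                "percent": 100.0 * n / total if total else 0.0,
            })
        if unlabeled:
            rows.append({"nucleus": nname, "territory": "unlabeled",
                         "n_significant": unlabeled,
                         "percent": 100.0 * unlabeled / total})
    return pd.DataFrame(rows)
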