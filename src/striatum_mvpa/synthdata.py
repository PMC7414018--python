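"""Synthetic phantom data for the striatal sequence-decoding pipeline.

The generator emits everything the downstream stages consume: four
ellipsoidal "nuclei" (left/right putamen and caudate) on a 2 mm grid, a
7-territory parcellation of each nucleus, per-(subject, run, sequence) beta
volumes, and button-press trial logs with a saturating learning curve.

The statistical structure of the beta maps is the point. Class identity is
carried by a sparse multivoxel pattern that is *exactly* mean-balanced
across classes at every voxel — so the sequences are discriminable from the
joint pattern while no single voxel has a class effect — on top of scalar
subject and run offsets, a smooth baseline activation map, and i.i.d.
Gaussian voxel noise (optionally smoothed). Subject and run offsets are
scalar per volume so that the demeaning stage removes them exactly, which
makes demeaning itself testable.

The class pattern for subject s is
``P_s = w * P_shared + (1 - w) * P_subject_s`` (w = ``subject_consistency``),
re-centered across classes per voxel after sampling so the univariate null
holds by construction, not just in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seeds import stage_rng
from .assembly import BetaDataset, MaskVolume, default_affine

NUCLEUS_NAMES = {1: "left_putamen", 2: "right_putamen",
                 3: "left_caudate", 4: "right_caudate"}
TERRITORY_NAMES = {1: "limbic", 2: "executive", 3: "rostral_motor",
                   4: "caudal_motor", 5: "parietal", 6: "occipital",
                   7: "temporal"}
# The six decoding ROIs: four nuclei plus per-hemisphere combinations.
ROI_DEFINITIONS = {
    "left_putamen": (1,), "right_putamen": (2,),
    "left_caudate": (3,), "right_caudate": (4,),
    "left_striatum": (1, 3), "right_striatum": (2, 4),
}

#: Five-press targets, one per sequence class. Class 1 is the simple
#: ascending sequence; classes 2-4 add direction changes and finger jumps.
SEQUENCES = {
    1: (1, 2, 3, 4, 5),
    2: (1, 3, 5, 4, 2),
    3: (2, 4, 1, 3, 5),
    4: (3, 1, 4, 2, 5),
}


@dataclass
class SyntheticDesign:
    n_subjects: int = 16
    n_runs: int = 6
    n_classes: int = 4
    analysis_runs: tuple | None = None   # default: the last (up to) 3 runs
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.analysis_runs is None:
            self.analysis_runs = tuple(
                range(max(1, self.n_runs - 2), self.n_runs + 1))
        self.analysis_runs = tuple(self.analysis_runs)
        if not set(self.analysis_runs) <= set(range(1, self.n_runs + 1)):
            raise ValueError("analysis_runs must be within 1..n_runs")

    @property
    def subjects(self):
        return list(range(1, self.n_subjects + 1))

    @property
    def runs(self):
        return list(range(1, self.n_runs + 1))

    @property
    def classes(self):
        return list(range(1, self.n_classes + 1))


@dataclass
class PatternSpec:
    """Amplitudes and noise of the synthetic beta maps.

    ``pattern_sd`` is the class-pattern amplitude tau (in beta units, i.e.
    units of the noise sd when ``noise_sd=1``). The default 1.1 was
    calibrated once so that whole-ROI decoding accuracy on the default
    16-subject design, measured with bias-free within-training-fold
    demeaning, lands in the upper-30s/low-40s percent range; see the
    methods note. ``subject_consistency`` is the fraction of the pattern shared
    across subjects; the default 0 makes patterns purely idiosyncratic,
    which keeps every voxel's univariate class effect exactly null while the
    pooled decoder can still exploit within-subject run-to-run reliability.
    """

    n_informative_voxels: int = 240
    pattern_sd: float = 1.1
    subject_consistency: float = 0.0
    noise_sd: float = 1.0
    subject_offset_sd: float = 0.5
    run_offset_sd: float = 0.25
    baseline_map_amplitude: float = 1.0
    smoothing_fwhm_mm: float = 0.0
    site: tuple | None = None   # plant the pattern at/near this grid voxel

    def __post_init__(self):
        for name in ("pattern_sd", "subject_offset_sd", "run_offset_sd",
                     "baseline_map_amplitude", "smoothing_fwhm_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.subject_consistency <= 1:
            raise ValueError("subject_consistency must be in [0, 1]")


@dataclass
class PhantomMaskSet:
    nuclei: MaskVolume       # codes 1..4, NUCLEUS_NAMES
    territories: MaskVolume  # codes 1..7 inside nuclei, TERRITORY_NAMES

    @property
    def grid_shape(self):
        return self.nuclei.grid_shape

    @property
    def voxel_size_mm(self):
        return self.nuclei.voxel_size_mm

    def nucleus_voxels(self, code: int) -> np.ndarray:
        return np.argwhere(self.nuclei.data == code)


# ---------------------------------------------------------------------------
# masks


def _ellipsoid(grid_shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=np.float64)
    d = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    return d <= 1.0


def generate_masks(grid_shape=(40, 48, 40), voxel_size_mm: float = 2.0,
                   seed: int = 0) -> PhantomMaskSet:
    """Four disjoint ellipsoidal nuclei, each cut into 7 territory sectors.

    Geometry scales with the grid; the seed jitters the nucleus centers by
    up to half a voxel so distinct seeds give distinct (but statistically
    equivalent) phantoms. Territories are assigned geometrically: four
    long-axis (y) slabs, the first three split dorsoventrally, which is a
    reproducible stand-in for a connectivity parcellation — sufficient for
    testing the territory quantification stage.
    """
    nx, ny, nz = grid_shape
    rng = stage_rng(seed, "masks")
    centers = {
        1: (0.28 * nx, 0.48 * ny, 0.45 * nz),   # left putamen
        2: (0.72 * nx, 0.48 * ny, 0.45 * nz),   # right putamen
        3: (0.42 * nx, 0.56 * ny, 0.68 * nz),   # left caudate
        4: (0.58 * nx, 0.56 * ny, 0.68 * nz),   # right caudate
    }
    semi = {
        1: (0.095 * nx, 0.18 * ny, 0.13 * nz),
        2: (0.095 * nx, 0.18 * ny, 0.13 * nz),
        3: (0.075 * nx, 0.19 * ny, 0.105 * nz),
        4: (0.075 * nx, 0.19 * ny, 0.105 * nz),
    }
    nuclei = np.zeros(grid_shape, dtype=np.int16)
    territories = np.zeros(grid_shape, dtype=np.int16)
    for code, name in NUCLEUS_NAMES.items():
        center = np.asarray(centers[code]) + rng.uniform(-0.5, 0.5, 3)
        ell = _ellipsoid(grid_shape, center, semi[code])
        ell &= nuclei == 0  # enforce disjointness (nuclei should not touch)
        coords = np.argwhere(ell)
        if coords.shape[0] < 7:
            raise ValueError(
                f"grid {grid_shape} too small to hold nucleus {name!r}")
        on_edge = ((coords == 0).any() or
                   (coords[:, 0] == nx - 1).any() or
                   (coords[:, 1] == ny - 1).any() or
                   (coords[:, 2] == nz - 1).any())
        if on_edge:
            raise ValueError(f"nucleus {name!r} does not fit inside the grid")
        nuclei[tuple(coords.T)] = code
        territories[tuple(coords.T)] = _territory_sectors(coords)
    affine = default_affine(voxel_size_mm)
    return PhantomMaskSet(
        MaskVolume(nuclei, affine, voxel_size_mm, dict(NUCLEUS_NAMES)),
        MaskVolume(territories, affine.copy(), voxel_size_mm,
                   dict(TERRITORY_NAMES)),
    )


def _territory_sectors(coords: np.ndarray) -> np.ndarray:
    """7-way geometric partition: 4 y-slabs, first three split by z."""
    y, z = coords[:, 1], coords[:, 2]
    edges = np.quantile(y, [0.25, 0.5, 0.75])
    slab = np.searchsorted(edges, y, side="right")  # 0..3
    codes = np.empty(len(coords), dtype=np.int16)
    # slab 0 (most rostral): limbic / executive; slab 1: rostral motor /
    # temporal; slab 2: caudal motor / occipital; slab 3: parietal.
    pairs = {0: (1, 2), 1: (3, 7), 2: (4, 6)}
    for s in range(4):
        sel = slab == s
        if s == 3:
            codes[sel] = 5
            continue
        ventral, dorsal = pairs[s]
        zmed = np.median(z[sel])
        codes[sel & (z <= zmed)] = ventral
        codes[sel & (z > zmed)] = dorsal
    return codes


def uniform_roi_mask(grid_shape, n_voxels: int,
                     voxel_size_mm: float = 2.0) -> MaskVolume:
    """A single compact ROI of exactly ``n_voxels``, for controlled tests.

    Takes the n voxels closest to the grid center (ties broken by scan
    order), label code 1.
    """
    total = int(np.prod(grid_shape))
    if n_voxels > total:
        raise ValueError("n_voxels exceeds the grid")
    idx = np.indices(grid_shape, dtype=np.float64)
    center = (np.asarray(grid_shape) - 1) / 2.0
    d = sum((idx[a] - center[a]) ** 2 for a in range(3))
    flat_order = np.argsort(d.ravel(), kind="stable")[:n_voxels]
    data = np.zeros(grid_shape, dtype=np.int16)
    data.ravel()[flat_order] = 1
    return MaskVolume(data, default_affine(voxel_size_mm), voxel_size_mm,
                      {1: "roi"})


# ---------------------------------------------------------------------------
# beta maps


def generate_beta_dataset(design: SyntheticDesign, mask: MaskVolume,
                          pattern: PatternSpec) -> BetaDataset:
    """Beta volumes with a mean-balanced multivoxel class pattern.

    beta(s, r, c, v) = baseline(v) + a_s + b_{s,r} + P_{s,c,v} + eps
    with eps ~ N(0, noise_sd^2) i.i.d. (optionally Gaussian-smoothed;
    smoothing touches the noise field only so the exact mean balance of P
    is preserved). The informative voxel set is recorded in ``truth``.
    """
    rng = stage_rng(design.seed, "betas")
    grid_shape = mask.grid_shape
    in_roi = np.argwhere(mask.binary())
    n_roi = in_roi.shape[0]
    if pattern.n_informative_voxels > n_roi:
        raise ValueError(
            f"n_informative_voxels={pattern.n_informative_voxels} exceeds "
            f"ROI size {n_roi}")

    if pattern.site is not None:
        d = ((in_roi - np.asarray(pattern.site)) ** 2).sum(axis=1)
        pick = np.argsort(d, kind="stable")[: pattern.n_informative_voxels]
    else:
        pick = rng.choice(n_roi, size=pattern.n_informative_voxels,
                          replace=False)
    info_coords = in_roi[pick]
    info_idx = tuple(info_coords.T)

    S, K = design.n_subjects, design.n_classes
    tau, w = pattern.pattern_sd, pattern.subject_consistency
    shared = rng.normal(0.0, tau, size=(1, K, len(pick)))
    subj = rng.normal(0.0, tau, size=(S, K, len(pick)))
    P = w * shared + (1 - w) * subj
    P -= P.mean(axis=1, keepdims=True)  # exact per-voxel balance over classes

    baseline = pattern.baseline_map_amplitude * gaussian_filter(
        rng.standard_normal(grid_shape), sigma=2.0)
    a_s = rng.normal(0.0, pattern.subject_offset_sd, size=S)
    b_sr = rng.normal(0.0, pattern.run_offset_sd, size=(S, design.n_runs))

    sigma_vox = (pattern.smoothing_fwhm_mm /
                 (2.0 * np.sqrt(2.0 * np.log(2.0))) / mask.voxel_size_mm
                 if pattern.smoothing_fwhm_mm > 0 else 0.0)
    volumes = {}
    for si, s in enumerate(design.subjects):
        for ri, r in enumerate(design.runs):
            for ci, c in enumerate(design.classes):
                noise = rng.normal(0.0, pattern.noise_sd, size=grid_shape)
                if sigma_vox > 0:
                    noise = gaussian_filter(noise, sigma=sigma_vox)
                vol = baseline + a_s[si] + b_sr[si, ri] + noise
                vol[info_idx] += P[si, ci]
                volumes[(s, r, c)] = vol.astype(np.float32)

    truth = {
        "informative_voxels": info_coords,
        "class_patterns": P,               # (S, K, n_informative)
        "design": {"n_subjects": S, "n_runs": design.n_runs,
                   "n_classes": K, "analysis_runs": list(design.analysis_runs),
                   "seed": design.seed},
        "pattern": {k: v for k, v in vars(pattern).items()},
        "subject_offsets": a_s,
        "run_offsets": b_sr,
    }
    return BetaDataset(volumes, mask.affine.copy(), mask.voxel_size_mm, truth)


# ---------------------------------------------------------------------------
# behaviour


@dataclass
class LearningParams:
    """Saturating learning curve for movement time and accuracy.

    Expected movement time in run r is
    ``mt_asymptote + (mt_initial - mt_asymptote) * exp(-r / tau_runs)``;
    the same decay shapes the per-run error probability. Sequence 1 (the
    simple ascending sequence) is executed faster and more accurately, as
    overlearned regular sequences are.
    """

    mt_initial_s: float = 2.0
    mt_asymptote_s: float = 1.0
    tau_runs: float = 1.5
    mt_jitter_sd: float = 0.12          # lognormal sd of trial MT
    error_prob_initial: float = 0.30
    error_prob_asymptote: float = 0.07
    class1_mt_advantage_s: float = 0.15
    class1_error_multiplier: float = 0.5
    trials_per_class_per_run: int = 12  # 4 trial blocks x 3 executions

    def __post_init__(self):
        if self.mt_initial_s <= 0 or self.mt_asymptote_s <= 0:
            raise ValueError("movement times must be positive")

    def expected_mt(self, run: int, cls: int = 2) -> float:
        mt = self.mt_asymptote_s + (
            self.mt_initial_s - self.mt_asymptote_s
        ) * np.exp(-run / self.tau_runs) if self.tau_runs > 0 else (
            self.mt_asymptote_s)
        if cls == 1:
            mt = max(mt - self.class1_mt_advantage_s, 0.05)
        # lognormal jitter multiplies by exp(N(0, sd^2)); correct the mean
        return float(mt) * float(np.exp(self.mt_jitter_sd ** 2 / 2.0))

    def error_prob(self, run: int, cls: int) -> float:
        p = self.error_prob_asymptote + (
            self.error_prob_initial - self.error_prob_asymptote
        ) * (np.exp(-run / self.tau_runs) if self.tau_runs > 0 else 0.0)
        if cls == 1:
            p *= self.class1_error_multiplier
        return float(np.clip(p, 0.0, 1.0))


def generate_press_log(design: SyntheticDesign,
                       params: LearningParams | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Trial log with 5 press events per trial.

    Error trials carry a non-identity permutation of the target button
    order; press times are strictly increasing within a trial and span the
    trial's movement time exactly.
    """
    params = params or LearningParams()
    rng = stage_rng(design.seed if seed is None else seed, "press_log")
    rows = []
    for s in design.subjects:
        for r in design.runs:
            trial = 0
            for c in design.classes:
                target = SEQUENCES[((c - 1) % 4) + 1]
                for _ in range(params.trials_per_class_per_run):
                    trial += 1
                    mt_mean = params.mt_asymptote_s + (
                        params.mt_initial_s - params.mt_asymptote_s
                    ) * (np.exp(-r / params.tau_runs)
                         if params.tau_runs > 0 else 0.0)
                    if c == 1:
                        mt_mean = max(mt_mean - params.class1_mt_advantage_s,
                                      0.05)
                    mt = mt_mean * np.exp(rng.normal(0, params.mt_jitter_sd))
                    if mt <= 0:
                        raise ValueError("nonpositive movement time")
                    buttons = list(target)
                    if rng.random() < params.error_prob(r, c):
                        while True:  # any non-identity permutation
                            perm = rng.permutation(5)
                            if not np.array_equal(perm, np.arange(5)):
                                break
                        buttons = [target[p] for p in perm]
                    t0 = rng.uniform(0.2, 0.5)
                    gaps = rng.dirichlet(np.ones(4)) * mt
                    times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
                    rows.append({"subject": s, "run": r, "trial": trial,
                                 "class": c,
                                 **{f"press{i+1}": buttons[i] for i in range(5)},
                                 **{f"t{i+1}": times[i] for i in range(5)}})
    return pd.DataFrame(rows)


def write_press_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)


def read_press_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
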