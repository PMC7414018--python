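import pytest

import striatum_mvpa as sm


def make_roi_dataset(n_voxels=20, n_subjects=4, n_runs=2, n_classes=4,
                     pattern_sd=0.0, seed=0, grid=(8, 8, 8), **pattern_kwargs):
    """Small single-ROI dataset for controlled tests."""
    design = sm.SyntheticDesign(
        n_subjects=n_subjects, n_runs=n_runs, n_classes=n_classes,
        analysis_runs=tuple(range(1, n_runs + 1)), seed=seed)
    mask = sm.uniform_roi_mask(grid, n_voxels)
    pattern_kwargs.setdefault("n_informative_voxels",
                              min(5, n_voxels) if pattern_sd else 0)
    pattern = sm.PatternSpec(pattern_sd=pattern_sd, **pattern_kwargs)
    dataset = sm.generate_beta_dataset(design, mask, pattern)
    return design, mask, dataset


def roi_samples(dataset, mask, demean=True, **kw):
    smat = sm.extract_roi_samples(dataset, mask, [1], **kw)
    return sm.demean_within_block(smat) if demean else smat


@pytest.fixture(scope="session")
def signal_samples():
    """48 samples x 20 voxels with a strong subject-specific pattern."""
    _, mask, dataset = make_roi_dataset(pattern_sd=2.0, seed=11,
                                        n_informative_voxels=8)
    return roi_samples(dataset, mask)


@pytest.fixture(scope="session")
def noise_samples():
    """Signal-free 48 x 20 matrix (class labels carry no information)."""
    _, mask, dataset = make_roi_dataset(pattern_sd=0.0, seed=12)
    return roi_samples(dataset, mask)
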