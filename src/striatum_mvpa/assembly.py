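"""Volumes, masks and sample-matrix assembly.

This module owns the three central containers — labelled mask volumes,
per-(subject, run, class) beta volumes, and the samples x voxels matrix that
all decoding operates on — plus the operations that connect them: group-mask
construction from individual masks, ROI extraction in a fixed voxel scan
order, and voxelwise demeaning within subject x run blocks.

Voxel column order
------------------
ROI columns are sorted by ascending linear index with x fastest,
``index = x + nx * (y + ny * z)``, so a weight vector can always be written
back onto the grid. Combined ROIs (several label codes) concatenate the
per-code column blocks in the order the codes were given.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

AFFINE_TOL = 1e-4  # float jitter seen in NIfTI headers


# ---------------------------------------------------------------------------
# containers


@dataclass
class MaskVolume:
    """Integer-labelled 3D volume. 0 is background."""

    data: np.ndarray                      # (nx, ny, nz) int
    affine: np.ndarray                    # 4x4 grid-to-world
    voxel_size_mm: float
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask volume must be 3D")
        if self.data.min() < 0:
            raise ValueError("mask labels must be nonnegative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def binary(self, codes=None) -> np.ndarray:
        """Boolean volume of the given label codes (default: any nonzero)."""
        if codes is None:
            return self.data > 0
        return np.isin(self.data, np.asarray(list(codes)))

    def code_for(self, name: str) -> int:
        for code, nm in self.labels.items():
            if nm == name:
                return code
        raise KeyError(f"no label named {name!r}")

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        img.header.set_zooms((self.voxel_size_mm,) * 3)
        nib.save(img, str(path))
        if self.labels:
            Path(str(path) + ".labels.json").write_text(
                json.dumps({str(k): v for k, v in self.labels.items()}, indent=1))

    @classmethod
    def load(cls, path) -> "MaskVolume":
        img = nib.load(str(path))
        labels = {}
        sidecar = Path(str(path) + ".labels.json")
        if sidecar.exists():
            labels = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine,
                   float(img.header.get_zooms()[0]), labels)


def default_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


@dataclass
class BetaDataset:
    """Per-(subject, run, class) beta volumes on a common grid.

    Volumes are stored float32; ``truth`` carries generator ground truth
    (informative voxel coordinates, parameters) when the dataset is
    synthetic and is empty for data read from disk without a sidecar.
    """

    volumes: dict[tuple[int, int, int], np.ndarray]
    affine: np.ndarray
    voxel_size_mm: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise ValueError(f"beta volumes on mixed grids: {sorted(shapes)}")

    @property
    def grid_shape(self):
        return next(iter(self.volumes.values())).shape

    @property
    def subjects(self):
        return sorted({s for s, _, _ in self.volumes})

    @property
    def runs(self):
        return sorted({r for _, r, _ in self.volumes})

    @property
    def classes(self):
        return sorted({c for _, _, c in self.volumes})

    def get(self, subject: int, run: int, cls: int) -> np.ndarray:
        return self.volumes[(subject, run, cls)]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (s, r, c), vol in self.volumes.items():
            img = nib.Nifti1Image(vol.astype(np.float32), self.affine)
            img.header.set_zooms((self.voxel_size_mm,) * 3)
            nib.save(img, directory / f"sub-{s:02d}_run-{r}_seq-{c}_beta.nii.gz")
        meta = {"voxel_size_mm": self.voxel_size_mm,
                "truth": _jsonable(self.truth)}
        (directory / "dataset.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "BetaDataset":
        directory = Path(directory)
        volumes = {}
        affine = None
        vox = None
        for f in sorted(directory.glob("sub-*_run-*_seq-*_beta.nii*")):
            parts = f.name.split("_")
            s = int(parts[0].split("-")[1])
            r = int(parts[1].split("-")[1])
            c = int(parts[2].split("-")[1])
            img = nib.load(str(f))
            if affine is None:
                affine = img.affine
                vox = float(img.header.get_zooms()[0])
            elif not np.allclose(img.affine, affine, atol=AFFINE_TOL):
                raise ValueError(f"grid mismatch in {f.name}")
            volumes[(s, r, c)] = np.asarray(img.dataobj, dtype=np.float32)
        if not volumes:
            raise FileNotFoundError(f"no beta volumes under {directory}")
        truth = {}
        meta = directory / "dataset.json"
        if meta.exists():
            truth = json.loads(meta.read_text()).get("truth", {})
        return cls(volumes, affine, vox, truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class SampleMatrix:
    """Samples x voxels matrix with per-sample annotations.

    Rows are ordered (subject, run, class) lexicographically; columns map
    back to grid coordinates through ``voxel_coords``.
    """

    values: np.ndarray        # (n_samples, n_voxels) float64
    subjects: np.ndarray      # (n_samples,)
    runs: np.ndarray
    labels: np.ndarray        # class labels
    voxel_coords: np.ndarray  # (n_voxels, 3) int
    grid_shape: tuple
    affine: np.ndarray
    voxel_size_mm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("sample matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select_classes(self, classes) -> "SampleMatrix":
        keep = np.isin(self.labels, np.asarray(list(classes)))
        return replace(self, values=self.values[keep],
                       subjects=self.subjects[keep], runs=self.runs[keep],
                       labels=self.labels[keep])

    def select_voxels(self, columns) -> "SampleMatrix":
        columns = np.asarray(columns)
        return replace(self, values=self.values[:, columns],
                       voxel_coords=self.voxel_coords[columns])

    def annotations(self) -> pd.DataFrame:
        return pd.DataFrame({"subject": self.subjects, "run": self.runs,
                             "class": self.labels})

    def row_to_volume(self, row: int) -> np.ndarray:
        """Write one sample's values back onto the grid (zeros elsewhere)."""
        return values_to_volume(self.values[row], self.voxel_coords,
                                self.grid_shape)

    def save(self, prefix) -> None:
        """TSV annotations + .npy matrix + voxel map, under a path prefix."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.annotations().to_csv(f"{prefix}_samples.tsv", sep="\t", index=False)
        np.save(f"{prefix}_values.npy", self.values)
        np.save(f"{prefix}_voxels.npy", self.voxel_coords)


def values_to_volume(values: np.ndarray, voxel_coords: np.ndarray,
                     grid_shape) -> np.ndarray:
    vol = np.zeros(grid_shape, dtype=np.float64)
    vol[tuple(voxel_coords.T)] = values
    return vol


# ---------------------------------------------------------------------------
# operations


def build_group_mask(individual_masks, overlap_threshold: float,
                     names=None) -> MaskVolume:
    """Group mask: voxels present in at least ``overlap_threshold`` of subjects.

    Inclusion rule: count/n >= threshold, so with 16 subjects and a 0.5
    threshold a voxel present in exactly 8 subjects is included.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    if not individual_masks:
        raise ValueError("no masks given")
    ref = individual_masks[0]
    names = names or [f"mask[{i}]" for i in range(len(individual_masks))]
    counts = np.zeros(ref.grid_shape, dtype=np.int32)
    for m, name in zip(individual_masks, names):
        if m.grid_shape != ref.grid_shape or not np.allclose(
                m.affine, ref.affine, atol=AFFINE_TOL):
            raise ValueError(f"grid mismatch for {name}")
        counts += m.binary().astype(np.int32)
    frac = counts / len(individual_masks)
    data = (frac >= overlap_threshold).astype(np.int16)
    return MaskVolume(data, ref.affine.copy(), ref.voxel_size_mm, {1: "group"})


def roi_voxel_coords(mask: MaskVolume, roi_codes) -> np.ndarray:
    """In-ROI voxel coordinates, per code, each block in x-fastest scan order."""
    nx, ny, _ = mask.grid_shape
    blocks = []
    for code in roi_codes:
        coords = np.argwhere(mask.data == code)
        if coords.size == 0:
            raise ValueError(f"ROI code {code} selects no voxels")
        lin = coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])
        blocks.append(coords[np.argsort(lin)])
    return np.concatenate(blocks, axis=0)


def extract_roi_samples(dataset: BetaDataset, mask: MaskVolume, roi_codes,
                        subjects=None, runs=None, classes=None) -> SampleMatrix:
    """One row per (subject, run, class); columns are in-ROI voxels.

    Combined ROIs are given as several codes; their column blocks are
    concatenated in the order the codes appear.
    """
    if mask.grid_shape != tuple(dataset.grid_shape) or not np.allclose(
            mask.affine, dataset.affine, atol=AFFINE_TOL):
        raise ValueError("mask and beta dataset are not on a common grid")
    subjects = list(subjects) if subjects is not None else dataset.subjects
    runs = list(runs) if runs is not None else dataset.runs
    classes = list(classes) if classes is not None else dataset.classes

    missing = [(s, r, c) for s in subjects for r in runs for c in classes
               if (s, r, c) not in dataset.volumes]
    if missing:
        raise KeyError(f"missing beta volumes for keys: {missing[:8]}"
                       + ("..." if len(missing) > 8 else ""))

    coords = roi_voxel_coords(mask, roi_codes)
    idx = tuple(coords.T)
    rows, subj_a, run_a, lab_a = [], [], [], []
    for s in subjects:
        for r in runs:
            for c in classes:
                rows.append(dataset.get(s, r, c)[idx].astype(np.float64))
                subj_a.append(s)
                run_a.append(r)
                lab_a.append(c)
    return SampleMatrix(np.array(rows), np.array(subj_a), np.array(run_a),
                        np.array(lab_a), coords, tuple(dataset.grid_shape),
                        dataset.affine.copy(), dataset.voxel_size_mm)


def demean_within_block(samples: SampleMatrix) -> SampleMatrix:
    """Subtract, per subject x run block, each voxel's mean across classes.

    Applied once to the full matrix before any training. Requires every
    block to contain each included class exactly once; removes any scalar
    (or voxelwise) offset shared by a block's samples. Idempotent.
    """
    values = samples.values.copy()
    classes = samples.classes
    block_ids = samples.subjects.astype(np.int64) * 1_000_003 + samples.runs
    for b in np.unique(block_ids):
        sel = block_ids == b
        if not np.array_equal(np.sort(samples.labels[sel]), classes):
            s = samples.subjects[sel][0]
            r = samples.runs[sel][0]
            raise ValueError(
                f"subject {s} run {r} block is incomplete: has classes "
                f"{sorted(samples.labels[sel])}, expected {list(classes)}")
        values[sel] -= values[sel].mean(axis=0, keepdims=True)
    return replace(samples, values=values)
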