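"""Image containers, NIfTI I/O, Gaussian smoothing and flattening.

The pipeline consumes spatially normalized tissue maps (whole-brain,
gray-matter and white-matter probability images) that share one voxel
grid across subjects.  This module holds the in-memory dataset, reads
subject tables that point at per-channel NIfTI files, applies isotropic
Gaussian smoothing, and flattens image stacks into the samples-by-voxels
feature matrix every downstream stage works on.

All computation happens in 0-based voxel coordinates; the NIfTI affine
is only carried along for round-tripping files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical channel names: whole-brain, gray matter, white matter.
CHANNELS = ("WB", "GM", "WM")

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_CHANNEL_ALIASES = {
    "wb": "WB", "whole-brain": "WB", "wholebrain": "WB", "whole_brain": "WB",
    "gm": "GM", "gray-matter": "GM", "gray_matter": "GM", "grey-matter": "GM",
    "wm": "WM", "white-matter": "WM", "white_matter": "WM",
}


def canonical_channel(name: str) -> str:
    """Map a channel name or alias to its canonical form (WB/GM/WM)."""
    key = str(name).strip().lower()
    if key in _CHANNEL_ALIASES:
        return _CHANNEL_ALIASES[key]
    raise ValueError(f"unknown tissue channel {name!r}; expected one of {CHANNELS}")


@dataclass
class ImageDataset:
    """Aligned per-subject 3D tissue maps plus labels and covariates.

    Parameters
    ----------
    subject_ids : list of str
        One identifier per subject; row order is authoritative everywhere.
    labels : ndarray of int, shape (S,)
        Class labels.  Binary tasks require exactly two distinct values.
    channels : dict mapping channel name -> ndarray, shape (S, X, Y, Z)
        One image stack per tissue channel, all on the same grid.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    covariates : DataFrame, shape (S, n_cov)
        Optional scalar covariates (e.g. MMSE), aligned to ``subject_ids``.
    """

    subject_ids: list[str]
    labels: np.ndarray
    channels: dict[str, np.ndarray]
    voxel_size_mm: float = 1.0
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.channels:
            raise ValueError("dataset needs at least one channel")
        self.channels = {canonical_channel(k): np.asarray(v, dtype=np.float64)
                         for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on array shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 4:
            raise ValueError("channel arrays must be (S, X, Y, Z)")
        s = shape[0]
        if len(self.subject_ids) != s or len(self.labels) != s:
            raise ValueError(
                f"subject table length {len(self.subject_ids)} does not match "
                f"image count {s}")
        if len(self.covariates) not in (0, s):
            raise ValueError("covariate table does not match subject count")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def subset(self, indices: Sequence[int]) -> "ImageDataset":
        """Row-subset of the dataset (copy-on-index)."""
        idx = np.asarray(indices)
        return ImageDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=self.labels[idx],
            channels={k: v[idx] for k, v in self.channels.items()},
            voxel_size_mm=self.voxel_size_mm,
            covariates=(self.covariates.iloc[idx].reset_index(drop=True)
                        if len(self.covariates) else pd.DataFrame()),
        )

    def binary_labels(self) -> np.ndarray:
        """Labels checked for exactly two classes."""
        values = np.unique(self.labels)
        if len(values) != 2:
            raise ValueError(
                f"binary task requires exactly two label values, got {values!r}")
        return self.labels


@dataclass
class FeatureMatrix:
    """Flattened samples-by-voxels matrix with its voxel bookkeeping.

    ``values`` has one row per subject (dataset row order) and one column
    per retained voxel; ``voxel_index`` maps each column back to its
    (i, j, k) grid coordinate so patterns can be scattered into 3D.
    """

    values: np.ndarray              # (S, M)
    channel: str
    fwhm_mm: float | None
    voxel_index: np.ndarray         # (M, 3) int
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index)
        if self.values.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("voxel_index length must equal column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def scatter(self, vector: np.ndarray) -> np.ndarray:
        """Place a length-M vector back onto the 3D grid (zeros elsewhere)."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"expected length-{self.n_voxels} vector, got {vector.shape}")
        out = np.zeros(self.grid_shape, dtype=np.float64)
        i, j, k = self.voxel_index.T
        out[i, j, k] = vector
        return out


# ---------------------------------------------------------------------------
# smoothing

def smooth_images(images: np.ndarray, fwhm_mm: float | None,
                  voxel_size_mm: float) -> np.ndarray:
    """Isotropic Gaussian smoothing of a (S, X, Y, Z) stack.

    ``fwhm_mm=None`` (or 0) returns the input unchanged.  The kernel
    sigma along each axis is ``fwhm / (voxel_size * 2*sqrt(2 ln 2))``
    voxels.  Boundaries use nearest-edge replication, which preserves the
    total intensity of interior signal and keeps constant images exactly
    constant.
    """
    images = np.asarray(images, dtype=np.float64)
    if fwhm_mm is None or fwhm_mm == 0:
        return images
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    sigma_vox = fwhm_mm / (voxel_size_mm * FWHM_PER_SIGMA)
    out = np.empty_like(images)
    for s in range(images.shape[0]):
        ndimage.gaussian_filter(images[s], sigma=sigma_vox, mode="nearest",
                                output=out[s])
    return out


def flatten(dataset: ImageDataset, channel: str, fwhm_mm: float | None = None,
            mask: np.ndarray | None = None) -> FeatureMatrix:
    """Smooth one channel and flatten it to a samples-by-voxels matrix.

    If ``mask`` is given only masked voxels are retained (columns ordered
    by C-order scan of the grid); ``voxel_index`` records their (i, j, k)
    coordinates.
    """
    channel = canonical_channel(channel)
    if channel not in dataset.channels:
        raise KeyError(f"channel {channel!r} not in dataset "
                       f"(has {dataset.channel_names})")
    stack = smooth_images(dataset.channels[channel], fwhm_mm,
                          dataset.voxel_size_mm)
    if mask is None:
        coords = np.indices(dataset.grid_shape).reshape(3, -1).T
        values = stack.reshape(dataset.n_subjects, -1)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dataset.grid_shape:
            raise ValueError("mask shape does not match the image grid")
        if not mask.any():
            raise ValueError("mask retains no voxels")
        coords = np.argwhere(mask)
        values = stack[:, mask]
    return FeatureMatrix(values=values, channel=channel, fwhm_mm=fwhm_mm,
                         voxel_index=coords, grid_shape=dataset.grid_shape,
                         voxel_size_mm=dataset.voxel_size_mm)


# ---------------------------------------------------------------------------
# NIfTI round-trip

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_nifti(array: np.ndarray, path: str | Path,
                voxel_size_mm: float = 1.0) -> Path:
    """Write a 3D array as a float32 NIfTI-1 image."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32),
                          _affine(voxel_size_mm))
    path = Path(path)
    nib.save(img, path)
    return path


def load_dataset(table: str | Path,
                 label_map: Mapping[str, int] | None = None,
                 channels: Sequence[str] | None = None) -> ImageDataset:
    """Load an ImageDataset from a subject table.

    The table is a CSV with columns ``subject_id``, ``label``, one
    ``path_<channel>`` column per tissue channel, and any further columns
    treated as scalar covariates.  Relative image paths are resolved
    against the table's directory.  ``label_map`` recodes string labels
    (e.g. ``{"AD": 1, "CN": 0}``).
    """
    table = Path(table)
    df = pd.read_csv(table)
    if "subject_id" not in df.columns or "label" not in df.columns:
        raise ValueError("subject table needs 'subject_id' and 'label' columns")
    path_cols = {c[len("path_"):]: c for c in df.columns if c.startswith("path_")}
    if channels is not None:
        wanted = {canonical_channel(c) for c in channels}
        path_cols = {k: v for k, v in path_cols.items()
                     if canonical_channel(k) in wanted}
    if not path_cols:
        raise ValueError("subject table has no path_<channel> columns")

    labels = df["label"]
    if label_map is not None:
        unmapped = set(labels.unique()) - set(label_map)
        if unmapped:
            raise ValueError(f"labels {sorted(map(str, unmapped))} missing from label_map")
        labels = labels.map(label_map)
    labels = labels.to_numpy()

    stacks: dict[str, np.ndarray] = {}
    shape: tuple[int, ...] | None = None
    voxel_size: float | None = None
    affine_ref: np.ndarray | None = None
    for ch_name, col in path_cols.items():
        imgs = []
        for sid, rel in zip(df["subject_id"], df[col]):
            p = Path(rel)
            if not p.is_absolute():
                p = table.parent / p
            if not p.exists():
                raise FileNotFoundError(f"image for subject {sid!r} not found: {p}")
            img = nib.load(str(p))
            data = np.asarray(img.dataobj, dtype=np.float64)
            if shape is None:
                shape = data.shape
                affine_ref = img.affine
                voxel_size = float(np.abs(img.affine[0, 0])) or 1.0
            elif data.shape != shape:
                raise ValueError(
                    f"subject {sid!r} image shape {data.shape} does not match "
                    f"the dataset grid {shape}")
            elif not np.allclose(img.affine, affine_ref, atol=1e-4):
                raise ValueError(f"subject {sid!r} affine differs from the dataset's")
            imgs.append(data)
        stacks[canonical_channel(ch_name)] = np.stack(imgs)

    cov_cols = [c for c in df.columns
                if c not in ("subject_id", "label") and not c.startswith("path_")]
    covariates = df[cov_cols].reset_index(drop=True) if cov_cols else pd.DataFrame()
    return ImageDataset(subject_ids=[str(s) for s in df["subject_id"]],
                        labels=labels, channels=stacks,
                        voxel_size_mm=voxel_size or 1.0, covariates=covariates)
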