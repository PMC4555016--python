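"""Synthetic two-group atrophy phantoms.

Generates pairs of subject groups on a shared 3D grid with a common
anatomical background, group-dependent intensity reduction ("atrophy")
inside configurable spherical regions of interest, and additive Gaussian
noise.  Because the signal location and size are known exactly, every
downstream stage — PCA ranking, classification accuracy, and the
back-projected discriminative maps — has a ground-truth surface to be
checked against.

The three tissue channels (WB, GM, WM) are carved from one background
realization using nested smooth radial masks, so the tissue-map
hyperparameter search is genuinely exercised; by default the atrophy is
injected only into the GM channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .images import (CHANNELS, ImageDataset, canonical_channel, smooth_images,
                     write_nifti)

#: Radial taper (inner edge, outer edge) of each channel mask, as a
#: fraction of the inscribed-sphere radius.  All three masks equal 1 at
#: the grid centre, so centred ROIs are visible in every channel.
_CHANNEL_TAPER = {"WB": (0.85, 0.95), "GM": (0.70, 0.85), "WM": (0.45, 0.60)}

_BACKGROUND_FWHM_MM = 8.0       # smoothing of the random-field background
_BACKGROUND_RANGE = (0.2, 1.0)  # intensity range after rescaling


@dataclass(frozen=True)
class ROISpec:
    """A spherical atrophy region: voxel-grid center, radius in mm, and
    fractional intensity reduction in group 1 (0 = no effect, 1 = total)."""

    center: tuple[int, int, int]
    radius_mm: float
    effect: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a two-group phantom dataset.

    Defaults describe the standard test phantom: a 20 voxel cube at 2 mm
    isotropic resolution, 30 subjects per group, one centred ROI of 8 mm
    radius with a 50% intensity reduction in group 1, a smooth random-field
    background shared by all subjects, and per-voxel Gaussian noise with
    standard deviation 0.05 (roughly 5% of the background intensity range).
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 2.0
    n_per_group: tuple[int, int] = (30, 30)
    effect_rois: tuple[ROISpec, ...] = (ROISpec((10, 10, 10), 8.0, 0.5),)
    background: str = "smooth"          # "smooth" or "flat"
    noise_sd: float = 0.05
    channels: tuple[str, ...] = CHANNELS
    effect_channels: tuple[str, ...] | None = None   # None -> GM if present
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(d <= 0 for d in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.background not in ("smooth", "flat"):
            raise ValueError("background must be 'smooth' or 'flat'")
        object.__setattr__(self, "channels",
                           tuple(canonical_channel(c) for c in self.channels))
        if self.effect_channels is not None:
            object.__setattr__(
                self, "effect_channels",
                tuple(canonical_channel(c) for c in self.effect_channels))
        rois = tuple(r if isinstance(r, ROISpec) else ROISpec(*r)
                     for r in self.effect_rois)
        object.__setattr__(self, "effect_rois", rois)
        bad = []
        for i, roi in enumerate(rois):
            if not (0.0 <= roi.effect <= 1.0):
                raise ValueError(f"ROI {i}: effect must lie in [0, 1]")
            r_vox = roi.radius_mm / self.voxel_size_mm
            if any(c - r_vox < 0 or c + r_vox > d - 1
                   for c, d in zip(roi.center, self.grid_shape)):
                bad.append(i)
        if bad:
            raise ValueError(f"ROI sphere(s) {bad} extend outside the grid")

    @property
    def resolved_effect_channels(self) -> tuple[str, ...]:
        if self.effect_channels is not None:
            return self.effect_channels
        return ("GM",) if "GM" in self.channels else self.channels


def _radial_fraction(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Distance from the grid centre as a fraction of the inscribed-sphere
    radius (1.0 at the nearest face)."""
    center = (np.asarray(grid_shape) - 1) / 2.0
    coords = np.indices(grid_shape).astype(np.float64)
    d = np.sqrt(sum((coords[a] - center[a]) ** 2 for a in range(3)))
    return d / (min(grid_shape) / 2.0)


def channel_mask(spec: PhantomSpec, channel: str) -> np.ndarray:
    """Smooth spatial weight in [0, 1] delimiting one tissue channel."""
    inner, outer = _CHANNEL_TAPER[canonical_channel(channel)]
    r = _radial_fraction(spec.grid_shape)
    return np.clip((outer - r) / (outer - inner), 0.0, 1.0)


def roi_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of all voxels inside any effect ROI (ground truth)."""
    mask = np.zeros(spec.grid_shape, dtype=bool)
    coords = np.indices(spec.grid_shape).astype(np.float64)
    for roi in spec.effect_rois:
        d = np.sqrt(sum((coords[a] - roi.center[a]) ** 2 for a in range(3)))
        mask |= d <= roi.radius_mm / spec.voxel_size_mm
    return mask


def _attenuation(spec: PhantomSpec) -> np.ndarray:
    """Multiplicative atrophy field for group 1: 1 - effect inside each
    sphere, with a linear one-voxel ramp at the boundary."""
    atten = np.ones(spec.grid_shape)
    coords = np.indices(spec.grid_shape).astype(np.float64)
    for roi in spec.effect_rois:
        d = np.sqrt(sum((coords[a] - roi.center[a]) ** 2 for a in range(3)))
        r_vox = roi.radius_mm / spec.voxel_size_mm
        depth = np.clip(r_vox - d, 0.0, 1.0)      # 1 inside, ramp at edge
        atten *= 1.0 - roi.effect * depth
    return atten


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.background == "flat":
        return np.ones(spec.grid_shape)
    raw = rng.standard_normal(spec.grid_shape)
    smoothed = smooth_images(raw[None], _BACKGROUND_FWHM_MM,
                             spec.voxel_size_mm)[0]
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo < 1e-12:         # pathological tiny grid; keep it flat
        return np.full(spec.grid_shape, np.mean(_BACKGROUND_RANGE))
    a, b = _BACKGROUND_RANGE
    return a + (b - a) * (smoothed - lo) / (hi - lo)


def generate_phantom(spec: PhantomSpec) -> ImageDataset:
    """Generate a two-group phantom ImageDataset.

    Group 0 images are ``background * channel_mask + noise``; group 1
    images additionally carry the multiplicative atrophy field inside the
    effect channels.  One background realization is shared by all
    subjects; noise is independent per subject and channel.  The output
    is bit-reproducible for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    background = _background(spec, rng)
    atten = _attenuation(spec)
    masks = {c: channel_mask(spec, c) for c in spec.channels}
    effect_on = set(spec.resolved_effect_channels)

    n0, n1 = spec.n_per_group
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    stacks = {c: np.empty((n0 + n1, *spec.grid_shape)) for c in spec.channels}
    for s, lab in enumerate(labels):
        for c in spec.channels:       # fixed order keeps the RNG stream stable
            base = background * masks[c]
            if lab == 1 and c in effect_on:
                base = background * atten * masks[c]
            noise = (rng.normal(0.0, spec.noise_sd, spec.grid_shape)
                     if spec.noise_sd > 0 else 0.0)
            stacks[c][s] = base + noise

    ids = [f"sub-{s:03d}" for s in range(n0 + n1)]
    return ImageDataset(subject_ids=ids, labels=labels, channels=stacks,
                        voxel_size_mm=spec.voxel_size_mm)


def write_phantom(dataset: ImageDataset, directory: str | Path) -> Path:
    """Write a phantom dataset to disk in the pipeline's input format.

    Emits one float32 NIfTI per subject per channel, a ``subjects.csv``
    table (subject_id, label, covariates, path_<channel> columns) and a
    plain-text ``manifest.txt``.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: list[dict[str, object]] = []
    for s, sid in enumerate(dataset.subject_ids):
        row: dict[str, object] = {"subject_id": sid,
                                  "label": int(dataset.labels[s])}
        for name in dataset.covariates.columns:
            row[name] = dataset.covariates.iloc[s][name]
        for c in dataset.channel_names:
            fname = f"{sid}_{c}.nii.gz"
            write_nifti(dataset.channels[c][s], directory / fname,
                        dataset.voxel_size_mm)
            row[f"path_{c}"] = fname
        rows.append(row)
    table_path = directory / "subjects.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)

    manifest = directory / "manifest.txt"
    lines = [
        f"n_subjects: {dataset.n_subjects}",
        f"channels: {','.join(dataset.channel_names)}",
        f"grid_shape: {'x'.join(map(str, dataset.grid_shape))}",
        f"voxel_size_mm: {dataset.voxel_size_mm}",
        f"table: {table_path.name}",
    ]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
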