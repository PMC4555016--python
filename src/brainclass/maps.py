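"""Voxel-based discriminative biomarker maps from trained fold models.

A linear classifier's weight vector is a *backward* model: its entries
are not directly interpretable as where the class signal lives, because
weights also serve to cancel correlated noise.  Following Haufe's
transformation for linear backward models, the weight vector w is mapped
to an activation pattern a = Cov(X) w (the scalar output-variance factor
of the general form A = Cov(X) W Cov(s)^-1 is absorbed by the final
[0, 1] rescaling).  The pattern, expressed in the selected FDR-ranked
component space, is back-projected through the PCA loadings to voxel
space, giving one map per cross-validation fold; fold maps are averaged
(on absolute values, since component signs are arbitrary across folds)
and min-max normalized to [0, 1] for thresholded overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .crossval import CVResult, FoldRecord
from .features import FDRRanking, PCAModel
from .images import write_nifti
from .svm import TrainedClassifier


@dataclass
class DiscriminativeMap:
    """A [0, 1]-normalized voxel-space discriminative pattern map."""

    values: np.ndarray              # 3D, min >= 0, max == 1
    n_folds_averaged: int
    comparison: str = ""
    threshold: float | None = None
    voxel_size_mm: float = 1.0

    def thresholded(self, threshold: float) -> "DiscriminativeMap":
        """Zero all voxels strictly below ``threshold``."""
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        vals = np.where(self.values >= threshold, self.values, 0.0)
        return DiscriminativeMap(values=vals,
                                 n_folds_averaged=self.n_folds_averaged,
                                 comparison=self.comparison,
                                 threshold=threshold,
                                 voxel_size_mm=self.voxel_size_mm)

    def top_voxels(self, q: int) -> np.ndarray:
        """Boolean mask of the q highest-valued voxels."""
        flat = self.values.ravel()
        idx = np.argpartition(-flat, q - 1)[:q]
        mask = np.zeros(flat.shape, dtype=bool)
        mask[idx] = True
        return mask.reshape(self.values.shape)


def feature_weight_vector(classifier: TrainedClassifier,
                          signed_by_label: bool = True) -> np.ndarray:
    """Aggregate the weighted support vectors into a feature-space vector.

    With ``signed_by_label`` (default) this is the primal weight vector
    sum_n w_n t_n x_n, which is invariant to class imbalance; setting it
    False drops the label factor and sums w_n x_n directly.
    """
    if signed_by_label:
        return classifier.primal_w.copy()
    return classifier.dual_weights @ classifier.training_features


def haufe_activation(weight: np.ndarray,
                     training_coefficients: np.ndarray) -> np.ndarray:
    """Haufe activation pattern a = Cov(X) w for a single-output model.

    ``training_coefficients`` are the classifier's training features
    (rows = samples); the covariance uses the unbiased 1/(S-1) estimator.
    """
    x = np.asarray(training_coefficients, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 training samples to estimate a covariance")
    weight = np.asarray(weight, dtype=np.float64)
    if weight.shape != (x.shape[1],):
        raise ValueError("weight length does not match the feature count")
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    return cov @ weight


def backproject(pattern: np.ndarray, model: PCAModel, ranking: FDRRanking,
                n_components: int) -> np.ndarray:
    """Transform a component-space pattern back to a 3D voxel map.

    ``pattern`` addresses the first ``n_components`` components in FDR
    order; unselected components contribute nothing.
    """
    pattern = np.asarray(pattern, dtype=np.float64)
    if pattern.shape != (n_components,):
        raise ValueError(
            f"pattern length {pattern.shape} does not match "
            f"n_components={n_components}")
    if model.voxel_index is None or model.grid_shape is None:
        raise ValueError("PCA model carries no voxel geometry to scatter into")
    selected = model.loadings[:, ranking.order[:n_components]]
    flat = selected @ pattern
    out = np.zeros(model.grid_shape, dtype=np.float64)
    i, j, k = np.asarray(model.voxel_index).T
    out[i, j, k] = flat
    return out


def fold_map(record: FoldRecord, signed_by_label: bool = True) -> np.ndarray:
    """Unnormalized voxel map for one cross-validation fold.

    The Haufe correction uses the covariance of the classifier's full
    training feature block (selected components plus any appended
    covariates); only the component entries of the pattern are
    back-projected — covariate entries have no voxel location.
    """
    w = feature_weight_vector(record.classifier, signed_by_label)
    pattern = haufe_activation(w, record.classifier.training_features)
    n = record.config.n_components
    return backproject(pattern[:n], record.pca, record.ranking, n)


def aggregate_maps(maps: Sequence[np.ndarray], comparison: str = "",
                   voxel_size_mm: float = 1.0) -> DiscriminativeMap:
    """Average per-fold maps and normalize to [0, 1].

    Averaging uses absolute values (per-fold maps can differ in global
    sign when folds select different configurations); normalization is
    min-max on the averaged map.
    """
    if len(maps) == 0:
        raise ValueError("no maps to aggregate")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps disagree on grid shape: {sorted(shapes)}")
    mean_map = np.mean([np.abs(m) for m in maps], axis=0)
    lo, hi = mean_map.min(), mean_map.max()
    if hi - lo <= 0:
        raise ValueError("degenerate (constant) mean map cannot be normalized")
    return DiscriminativeMap(values=(mean_map - lo) / (hi - lo),
                             n_folds_averaged=len(maps),
                             comparison=comparison,
                             voxel_size_mm=voxel_size_mm)


def compute_discriminative_map(result: CVResult, comparison: str = "",
                               signed_by_label: bool = True
                               ) -> DiscriminativeMap:
    """Final averaged discriminative map from a nested-CV result."""
    maps = [fold_map(f, signed_by_label) for f in result.folds]
    return aggregate_maps(maps, comparison=comparison,
                          voxel_size_mm=result.voxel_size_mm)


def threshold_and_export(dmap: DiscriminativeMap, threshold: float,
                         out: str | Path,
                         reference_nifti: str | Path | None = None) -> Path:
    """Threshold a map and write it as float32 NIfTI.

    With a ``reference_nifti`` the reference affine is reused (for
    overlay on a standard brain); otherwise a diagonal affine from the
    map's voxel size is written.
    """
    thr = dmap.thresholded(threshold)
    out = Path(out)
    if reference_nifti is not None:
        ref = nib.load(str(reference_nifti))
        img = nib.Nifti1Image(np.asarray(thr.values, dtype=np.float32),
                              ref.affine)
        nib.save(img, out)
        return out
    return write_nifti(thr.values, out, dmap.voxel_size_mm)
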