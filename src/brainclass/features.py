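"""PCA feature extraction and Fisher-Discriminant-Ratio component ranking.

With far more voxels than subjects (N >> S) the sample covariance of the
flattened image matrix is rank-deficient, so the principal components are
obtained from the eigendecomposition of the S x S Gram matrix of the
centered data; at most S - 1 components have non-zero eigenvalues.  Each
subject is then represented by its PCA coefficients (projections onto the
components), and components are ranked for class-discriminative power by
the Fisher Discriminant Ratio

    FDR = (mu_1 - mu_2)^2 / (sigma_1^2 + sigma_2^2)

computed per component from the class means and variances of its
coefficients.  Note: FDR here is the class-separability score, not the
false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import FeatureMatrix

#: Components with eigenvalue <= RANK_TOL * largest eigenvalue are
#: treated as numerically zero and dropped.
RANK_TOL = 1e-10


@dataclass
class PCAModel:
    """A fitted PCA basis.

    ``loadings`` columns are orthonormal principal components in voxel
    space; ``eigenvalues`` are the matching sample-covariance eigenvalues
    in descending order.  ``voxel_index``/``grid_shape`` are carried from
    the training FeatureMatrix so patterns can be scattered back to 3D.
    """

    mean: np.ndarray                # (N,)
    loadings: np.ndarray            # (N, PC), orthonormal columns
    eigenvalues: np.ndarray         # (PC,), descending
    voxel_index: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class FDRRanking:
    """Per-component Fisher Discriminant Ratios and the induced order."""

    scores: np.ndarray              # (PC,)
    order: np.ndarray               # permutation of 0..PC-1, scores descending
    class_means: np.ndarray         # (2, PC): mu_1, mu_2
    class_vars: np.ndarray          # (2, PC): sigma_1^2, sigma_2^2 (unbiased)


def _as_values(data) -> np.ndarray:
    return data.values if isinstance(data, FeatureMatrix) else np.asarray(data, float)


def fit_pca(train: FeatureMatrix | np.ndarray, rank_tol: float = RANK_TOL) -> PCAModel:
    """Fit PCA on the training matrix via the S x S Gram matrix.

    The loadings are eigenvectors of the sample covariance (1/(S-1)
    normalization) of the centered data, recovered from the Gram-matrix
    eigendecomposition — never forming the N x N covariance.  Components
    with eigenvalues at or below ``rank_tol`` times the largest are
    dropped, which enforces the PC <= S - 1 rank bound.  Column signs are
    fixed so the largest-magnitude loading entry is positive.
    """
    x = _as_values(train)
    s = x.shape[0]
    if s < 2:
        raise ValueError("PCA needs at least 2 training samples")
    mean = x.mean(axis=0)
    xc = x - mean
    gram = (xc @ xc.T) / (s - 1)
    evals, evecs = np.linalg.eigh(gram)            # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    if evals[0] <= 0:
        raise ValueError("degenerate dataset: all samples identical after centering")
    keep = evals > rank_tol * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    # covariance eigenvector v_j = Xc^T u_j / sqrt((S-1) * lambda_j)
    loadings = xc.T @ (evecs / np.sqrt((s - 1) * evals))
    # deterministic sign: largest-|entry| of each loading made positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    loadings *= flip
    model = PCAModel(mean=mean, loadings=loadings, eigenvalues=evals)
    if isinstance(train, FeatureMatrix):
        model.voxel_index = train.voxel_index
        model.grid_shape = train.grid_shape
    return model


def project(model: PCAModel, samples: FeatureMatrix | np.ndarray) -> np.ndarray:
    """PCA coefficients of samples: ``(X - mean) @ loadings``.

    Applies identically to training and unseen samples.
    """
    x = _as_values(samples)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match the model's "
            f"{model.mean.shape[0]}")
    return (x - model.mean) @ model.loadings


def reconstruct(model: PCAModel, coefficients: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project` for full-rank coefficient vectors."""
    coefficients = np.atleast_2d(coefficients)
    return coefficients @ model.loadings.T + model.mean


def fdr_rank(coefficients: np.ndarray, labels: np.ndarray) -> FDRRanking:
    """Rank components by Fisher Discriminant Ratio, descending.

    Class variances use the unbiased (ddof=1) estimator, hence each class
    needs at least 2 members.  Ties (and zero-FDR components) break toward
    the lower original component index, keeping runs reproducible.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"FDR ranking needs exactly 2 classes, got {classes!r}")
    a, b = (coefficients[labels == c] for c in classes)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 members to estimate a variance")
    mu = np.stack([a.mean(axis=0), b.mean(axis=0)])
    var = np.stack([a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)])
    denom = var.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (mu[0] - mu[1]) ** 2 / denom
    scores = np.where(denom > 0, scores, np.inf)   # zero-variance, separated
    scores = np.where((denom == 0) & (mu[0] == mu[1]), 0.0, scores)
    order = np.argsort(-scores, kind="stable")
    return FDRRanking(scores=scores, order=order, class_means=mu, class_vars=var)


def explained_variance_curve(model: PCAModel,
                             ranking: FDRRanking | None = None) -> np.ndarray:
    """Cumulative explained-variance fraction per component count.

    With a ranking, eigenvalues are accumulated in FDR order instead of
    eigenvalue order; either way the curve is nondecreasing and ends at 1.
    """
    ev = model.eigenvalues
    if ranking is not None:
        if len(ranking.order) != len(ev):
            raise ValueError("ranking does not match the model's component count")
        ev = ev[ranking.order]
    return np.cumsum(ev) / ev.sum()


def variance_at_k(model: PCAModel, ranking: FDRRanking | None, k: int) -> float:
    """The (FDR-sorted) cumulative explained-variance fraction at k components."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range 1..{model.n_components}")
    return float(explained_variance_curve(model, ranking)[k - 1])
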