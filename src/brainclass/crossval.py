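"""Nested k-fold cross-validation over (tissue, smoothing, components).

The outer loop estimates generalization performance on held-out folds;
for each outer fold an inner split-half loop selects the hyperparameter
configuration — tissue map, smoothing FWHM, and number of FDR-ranked PCA
components — that minimizes the validation classification error
E = 1 - Balanced Accuracy.  PCA, FDR ranking and covariate
standardization are always fit on training samples only, so no statistic
from an outer test subject ever leaks into the model that predicts it.

Smoothing and flattening are per-image operations, so they are computed
once per (tissue, FWHM) combination for the whole dataset and folds
simply index rows of the cached matrix; this is mathematically identical
to smoothing inside each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import features as feat
from . import svm
from .images import FeatureMatrix, ImageDataset, canonical_channel, flatten

#: Default hyperparameter grid: smoothing FWHM in mm (None = no smoothing).
DEFAULT_FWHMS: tuple[float | None, ...] = (None, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
DEFAULT_TISSUES: tuple[str, ...] = ("WB", "GM", "WM")

#: Tie-break order between tissues at equal validation error.
_TISSUE_RANK = {"GM": 0, "WB": 1, "WM": 2}


@dataclass(frozen=True)
class ParamConfig:
    """One point of the hyperparameter grid."""

    tissue: str
    fwhm_mm: float | None
    n_components: int


@dataclass(frozen=True)
class ParamGrid:
    """Hyperparameter search space.

    ``max_components`` optionally caps the component sweep (the default
    searches 1..PC as extracted on the inner training half).
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    fwhms: tuple[float | None, ...] = DEFAULT_FWHMS
    max_components: int | None = None

    def __post_init__(self) -> None:
        if not self.tissues or not self.fwhms:
            raise ValueError("parameter grids must be nonempty")
        object.__setattr__(self, "tissues",
                           tuple(canonical_channel(t) for t in self.tissues))


def _config_sort_key(e: float, cfg: ParamConfig) -> tuple:
    """Minimized lexicographically: E, then fewer components, then smaller
    FWHM (with 'none' < 2 mm), then tissue order GM < WB < WM."""
    fwhm = -1.0 if cfg.fwhm_mm is None else float(cfg.fwhm_mm)
    return (e, cfg.n_components, fwhm, _TISSUE_RANK[cfg.tissue])


@dataclass
class FoldRecord:
    """Everything retained from one outer fold: the chosen configuration,
    the fitted artifacts, and the held-out evaluation."""

    fold_index: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    config: ParamConfig
    inner_E: float
    evaluation: svm.FoldEvaluation
    decisions: np.ndarray
    predicted: np.ndarray
    pca: feat.PCAModel
    ranking: feat.FDRRanking
    classifier: svm.TrainedClassifier
    covariate_stats: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class CVResult:
    """Result of a nested cross-validation run."""

    folds: list[FoldRecord]
    k: int
    seed: int
    refit: str
    labels: np.ndarray
    positive_class: object
    voxel_size_mm: float = 1.0

    @property
    def fold_balanced_accuracies(self) -> np.ndarray:
        return np.array([f.evaluation.balanced_accuracy for f in self.folds])

    @property
    def overall_balanced_accuracy(self) -> float:
        """Arithmetic mean of the per-fold balanced accuracies."""
        return float(self.fold_balanced_accuracies.mean())

    @property
    def balanced_accuracy_sd(self) -> float:
        return float(self.fold_balanced_accuracies.std(ddof=1))

    def pooled_evaluation(self) -> svm.FoldEvaluation:
        """Evaluation of all outer-fold predictions pooled together."""
        y_true = np.concatenate([self.labels[f.test_indices] for f in self.folds])
        y_pred = np.concatenate([f.predicted for f in self.folds])
        return svm.evaluate(y_true, y_pred, self.positive_class)

    def fold_table(self) -> pd.DataFrame:
        """Per-fold summary: E, tissue map, smoothing FWHM, components."""
        rows = []
        for f in self.folds:
            rows.append({
                "fold": f.fold_index,
                "E": f.evaluation.E,
                "tissue_map": f.config.tissue,
                "smoothing_fwhm_mm": (0.0 if f.config.fwhm_mm is None
                                      else f.config.fwhm_mm),
                "pca_coefficients": f.config.n_components,
                "balanced_accuracy": f.evaluation.balanced_accuracy,
                "sensitivity": f.evaluation.sensitivity,
                "specificity": f.evaluation.specificity,
                "inner_E": f.inner_E,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "refit": self.refit,
            "overall_balanced_accuracy": self.overall_balanced_accuracy,
            "balanced_accuracy_sd": self.balanced_accuracy_sd,
            "pooled_balanced_accuracy": self.pooled_evaluation().balanced_accuracy,
        }


def make_folds(labels: np.ndarray, k: int, seed: int
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified partition into k folds (sizes differ by <= 1 per class)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(labels)), labels)]


def _feature_cache(dataset: ImageDataset, grid: ParamGrid,
                   mask: np.ndarray | None = None
                   ) -> dict[tuple[str, float | None], FeatureMatrix]:
    return {(t, f): flatten(dataset, t, f, mask)
            for t in grid.tissues for f in grid.fwhms}


def _covariate_block(dataset: ImageDataset,
                     covariates: Sequence[str] | None) -> np.ndarray | None:
    if not covariates:
        return None
    missing = [c for c in covariates if c not in dataset.covariates.columns]
    if missing:
        raise ValueError(f"covariate column(s) {missing} not in the dataset")
    return dataset.covariates[list(covariates)].to_numpy(dtype=np.float64)


def _inner_optimize(cache, labels, inner_idx, grid: ParamGrid, seed: int,
                    cov_block: np.ndarray | None, C: float,
                    positive_class) -> tuple[ParamConfig, float, dict]:
    """Split-half search over the grid; returns the E-minimizing config,
    its validation error, and the half-trained artifacts."""
    inner_idx = np.asarray(inner_idx)
    y_inner = labels[inner_idx]
    classes, counts = np.unique(y_inner, return_counts=True)
    if len(inner_idx) < 4 or len(classes) != 2 or counts.min() < 4:
        raise ValueError(
            "inner optimization needs >= 4 subjects per class so each "
            "stratified half keeps >= 2 per class")
    tr_idx, va_idx = train_test_split(inner_idx, test_size=0.5,
                                      stratify=y_inner, random_state=seed)
    y_tr, y_va = labels[tr_idx], labels[va_idx]

    best_key = None
    best: tuple[ParamConfig, float, dict] | None = None
    for tissue in grid.tissues:
        for fwhm in grid.fwhms:
            fm = cache[(tissue, fwhm)]
            x_tr, x_va = fm.values[tr_idx], fm.values[va_idx]
            pca = feat.fit_pca(x_tr)
            coeff_tr = feat.project(pca, x_tr)
            ranking = feat.fdr_rank(coeff_tr, y_tr)
            coeff_va = feat.project(pca, x_va)
            sorted_tr = coeff_tr[:, ranking.order]
            sorted_va = coeff_va[:, ranking.order]
            cov_stats = None
            if cov_block is not None:
                cov_stats = svm.covariate_stats(cov_block[tr_idx])
            n_max = pca.n_components
            if grid.max_components is not None:
                n_max = min(n_max, grid.max_components)
            for n in range(1, n_max + 1):
                f_tr, f_va = sorted_tr[:, :n], sorted_va[:, :n]
                if cov_block is not None:
                    f_tr = svm.augment_with_covariates(
                        f_tr, cov_block[tr_idx], *cov_stats)
                    f_va = svm.augment_with_covariates(
                        f_va, cov_block[va_idx], *cov_stats)
                clf = svm.train(f_tr, y_tr, C=C, positive_class=positive_class)
                _, pred = svm.predict(clf, f_va)
                e = svm.evaluate(y_va, pred, clf.positive_class).E
                cfg = ParamConfig(tissue, fwhm, n)
                key = _config_sort_key(e, cfg)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (cfg, e, {
                        "pca": pca, "ranking": ranking, "classifier": clf,
                        "cov_stats": cov_stats, "train_half": tr_idx,
                        "feature_matrix": fm,
                    })
    assert best is not None
    return best


def inner_optimize(dataset: ImageDataset, grid: ParamGrid | None = None,
                   seed: int = 0, covariates: Sequence[str] | None = None,
                   C: float = svm.DEFAULT_C, positive_class=None,
                   mask: np.ndarray | None = None
                   ) -> tuple[ParamConfig, float, dict]:
    """Run the inner split-half hyperparameter search on a dataset."""
    grid = grid or ParamGrid()
    labels = dataset.binary_labels()
    cache = _feature_cache(dataset, grid, mask)
    cov_block = _covariate_block(dataset, covariates)
    return _inner_optimize(cache, labels, np.arange(dataset.n_subjects),
                           grid, seed, cov_block, C, positive_class)


def _attach_geometry(pca: feat.PCAModel, fm: FeatureMatrix) -> None:
    pca.voxel_index = fm.voxel_index
    pca.grid_shape = fm.grid_shape


def run_nested_cv(dataset: ImageDataset, k: int = 20,
                  grid: ParamGrid | None = None, seed: int = 0,
                  refit: str = "full",
                  covariates: Sequence[str] | None = None,
                  C: float = svm.DEFAULT_C, positive_class=None,
                  mask: np.ndarray | None = None) -> CVResult:
    """Nested k-fold cross-validation.

    For each outer fold the inner split-half search picks a configuration;
    with ``refit="full"`` (default) PCA, FDR ranking, covariate statistics
    and the classifier are then refit on the entire inner set under that
    configuration before predicting the held-out fold; ``refit="half"``
    reuses the half-trained model directly.
    """
    if refit not in ("full", "half"):
        raise ValueError("refit must be 'full' or 'half'")
    grid = grid or ParamGrid()
    labels = dataset.binary_labels()
    if positive_class is None:
        positive_class = sorted(np.unique(labels).tolist())[1]
    cache = _feature_cache(dataset, grid, mask)
    cov_block = _covariate_block(dataset, covariates)
    folds = make_folds(labels, k, seed)

    records: list[FoldRecord] = []
    for i, (train_idx, test_idx) in enumerate(folds):
        cfg, inner_e, art = _inner_optimize(
            cache, labels, train_idx, grid, seed + i, cov_block, C,
            positive_class)
        fm = cache[(cfg.tissue, cfg.fwhm_mm)]
        if refit == "full":
            x_in = fm.values[train_idx]
            y_in = labels[train_idx]
            pca = feat.fit_pca(x_in)
            coeff_in = feat.project(pca, x_in)
            ranking = feat.fdr_rank(coeff_in, y_in)
            n = min(cfg.n_components, pca.n_components)
            cfg = ParamConfig(cfg.tissue, cfg.fwhm_mm, n)
            f_in = coeff_in[:, ranking.order][:, :n]
            cov_stats = None
            if cov_block is not None:
                cov_stats = svm.covariate_stats(cov_block[train_idx])
                f_in = svm.augment_with_covariates(
                    f_in, cov_block[train_idx], *cov_stats)
            clf = svm.train(f_in, y_in, C=C, positive_class=positive_class)
        else:
            pca = art["pca"]
            ranking = art["ranking"]
            clf = art["classifier"]
            cov_stats = art["cov_stats"]
        _attach_geometry(pca, fm)

        coeff_te = feat.project(pca, fm.values[test_idx])
        f_te = coeff_te[:, ranking.order][:, :cfg.n_components]
        if cov_block is not None:
            f_te = svm.augment_with_covariates(
                f_te, cov_block[test_idx], *cov_stats)
        decisions, pred = svm.predict(clf, f_te)
        evaluation = svm.evaluate(labels[test_idx], pred, positive_class)
        records.append(FoldRecord(
            fold_index=i, train_indices=np.asarray(train_idx),
            test_indices=np.asarray(test_idx), config=cfg, inner_E=inner_e,
            evaluation=evaluation, decisions=decisions, predicted=pred,
            pca=pca, ranking=ranking, classifier=clf,
            covariate_stats=cov_stats))

    return CVResult(folds=records, k=k, seed=seed, refit=refit, labels=labels,
                    positive_class=positive_class,
                    voxel_size_mm=dataset.voxel_size_mm)
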