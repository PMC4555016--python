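"""On-disk bundle for cross-validation results.

A bundle is a directory holding one compressed ``.npz`` of arrays per
outer fold plus a ``meta.json`` with everything scalar (chosen
configurations, confusion counts, seeds).  It lets the `maps` and
`predict` commands reuse fitted fold models without rerunning the
cross-validation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .crossval import CVResult, FoldRecord, ParamConfig
from .features import FDRRanking, PCAModel
from .svm import FoldEvaluation, TrainedClassifier

_FORMAT = "brainclass-cv-bundle-v1"


def save_cv_result(result: CVResult, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fold_meta = []
    for f in result.folds:
        arrays = {
            "pca_mean": f.pca.mean,
            "loadings": f.pca.loadings,
            "eigenvalues": f.pca.eigenvalues,
            "voxel_index": f.pca.voxel_index,
            "ranking_scores": f.ranking.scores,
            "ranking_order": f.ranking.order,
            "class_means": f.ranking.class_means,
            "class_vars": f.ranking.class_vars,
            "dual_weights": f.classifier.dual_weights,
            "label_signs": f.classifier.label_signs,
            "training_features": f.classifier.training_features,
            "primal_w": f.classifier.primal_w,
            "support_flags": f.classifier.support_flags,
            "train_indices": f.train_indices,
            "test_indices": f.test_indices,
            "decisions": f.decisions,
            "predicted": np.asarray(f.predicted),
        }
        if f.covariate_stats is not None:
            arrays["cov_mean"], arrays["cov_sd"] = f.covariate_stats
        np.savez_compressed(directory / f"fold_{f.fold_index:02d}.npz", **arrays)
        ev = f.evaluation
        fold_meta.append({
            "fold_index": f.fold_index,
            "tissue": f.config.tissue,
            "fwhm_mm": f.config.fwhm_mm,
            "n_components": f.config.n_components,
            "inner_E": f.inner_E,
            "confusion": [ev.tp, ev.tn, ev.fp, ev.fn],
            "bias": f.classifier.bias,
            "C": f.classifier.C,
            "grid_shape": list(f.pca.grid_shape),
            "has_covariates": f.covariate_stats is not None,
        })
    meta = {
        "format": _FORMAT,
        "k": result.k,
        "seed": result.seed,
        "refit": result.refit,
        "labels": np.asarray(result.labels).tolist(),
        "positive_class": _jsonable(result.positive_class),
        "voxel_size_mm": result.voxel_size_mm,
        "folds": fold_meta,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def _jsonable(v):
    return v.item() if isinstance(v, np.generic) else v


def load_cv_result(directory: str | Path) -> CVResult:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    if meta.get("format") != _FORMAT:
        raise ValueError(f"{directory} is not a brainclass CV bundle")
    labels = np.asarray(meta["labels"])
    pos = meta["positive_class"]
    classes = sorted(np.unique(labels).tolist())
    neg = classes[0] if classes[1] == pos else classes[1]

    folds = []
    for fm in meta["folds"]:
        z = np.load(directory / f"fold_{fm['fold_index']:02d}.npz")
        pca = PCAModel(mean=z["pca_mean"], loadings=z["loadings"],
                       eigenvalues=z["eigenvalues"],
                       voxel_index=z["voxel_index"],
                       grid_shape=tuple(fm["grid_shape"]))
        ranking = FDRRanking(scores=z["ranking_scores"],
                             order=z["ranking_order"],
                             class_means=z["class_means"],
                             class_vars=z["class_vars"])
        clf = TrainedClassifier(
            dual_weights=z["dual_weights"], label_signs=z["label_signs"],
            bias=fm["bias"], training_features=z["training_features"],
            primal_w=z["primal_w"], support_flags=z["support_flags"],
            positive_class=pos, negative_class=neg, C=fm["C"])
        tp, tn, fp, fn = fm["confusion"]
        cov_stats = ((z["cov_mean"], z["cov_sd"])
                     if fm["has_covariates"] else None)
        folds.append(FoldRecord(
            fold_index=fm["fold_index"], train_indices=z["train_indices"],
            test_indices=z["test_indices"],
            config=ParamConfig(fm["tissue"], fm["fwhm_mm"], fm["n_components"]),
            inner_E=fm["inner_E"],
            evaluation=FoldEvaluation(tp=tp, tn=tn, fp=fp, fn=fn),
            decisions=z["decisions"], predicted=z["predicted"],
            pca=pca, ranking=ranking, classifier=clf,
            covariate_stats=cov_stats))
    return CVResult(folds=folds, k=meta["k"], seed=meta["seed"],
                    refit=meta["refit"], labels=labels, positive_class=pos,
                    voxel_size_mm=meta["voxel_size_mm"])
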