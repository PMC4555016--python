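"""Linear maximum-margin classification on selected PCA coefficients.

The decision function is the standard support-vector form

    y(x) = sum_n w_n * t_n * k(x, x_n) + b,      k(x, x') = x . x'

with nonnegative dual weights w_n (nonzero only on support vectors),
class labels t_n in {-1, +1} and bias b.  With a linear kernel this is
identical to the primal form w . x + b with w = sum_n w_n t_n x_n; both
routes are exposed and their agreement is an invariant of every trained
model.  The quadratic program is solved by scikit-learn's SVC; this
module owns the dual bookkeeping, the decision-function contract, and
the balanced-accuracy metrics

    Balanced Accuracy = (Sensitivity + Specificity) / 2,   E = 1 - BA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

#: Soft-margin regularization constant; kept out of the hyperparameter
#: grid (the cross-validated search covers tissue, smoothing, components).
DEFAULT_C = 1.0


@dataclass
class TrainedClassifier:
    """A trained linear max-margin model in dual and primal form."""

    dual_weights: np.ndarray        # (S_train,), w_n >= 0, zero off support
    label_signs: np.ndarray         # (S_train,), t_n in {-1, +1}
    bias: float
    training_features: np.ndarray   # (S_train, d)
    primal_w: np.ndarray            # (d,) = sum_n w_n t_n x_n
    support_flags: np.ndarray       # (S_train,) bool
    positive_class: object          # original label mapped to t = +1
    negative_class: object
    C: float = DEFAULT_C

    @property
    def n_support(self) -> int:
        return int(self.support_flags.sum())


@dataclass
class FoldEvaluation:
    """Confusion counts and the derived balanced-accuracy metrics."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def E(self) -> float:
        return 1.0 - self.balanced_accuracy


def train(features: np.ndarray, labels: np.ndarray,
          C: float = DEFAULT_C, positive_class=None,
          tol: float = 1e-8) -> TrainedClassifier:
    """Train the soft-margin linear classifier.

    ``labels`` may use any two values; ``positive_class`` picks which one
    maps to t = +1 (default: the larger under sorting).  Deterministic
    for fixed inputs.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be a 2D matrix with >= 1 column")
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    if positive_class is None:
        positive_class = classes[1]
    elif positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in labels")
    negative_class = classes[0] if classes[1] == positive_class else classes[1]
    t = np.where(labels == positive_class, 1, -1)

    # tight stopping tolerance keeps the dual solution symmetric under
    # label flips and reproducible across runs
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(x, t)

    w = np.zeros(len(t))
    # dual_coef_ = alpha_n * t_n on support vectors; alpha_n > 0, so
    # |dual_coef_| recovers the nonnegative dual weight.
    w[clf.support_] = np.abs(clf.dual_coef_[0])
    support = w > 0
    primal_w = (w * t) @ x
    return TrainedClassifier(dual_weights=w, label_signs=t,
                             bias=float(clf.intercept_[0]),
                             training_features=x, primal_w=primal_w,
                             support_flags=support,
                             positive_class=positive_class,
                             negative_class=negative_class, C=C)


def decision_function(classifier: TrainedClassifier,
                      features: np.ndarray) -> np.ndarray:
    """Decision values via the dual form sum_n w_n t_n <x, x_n> + b."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != classifier.training_features.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match the trained "
            f"model's {classifier.training_features.shape[1]}")
    coeff = classifier.dual_weights * classifier.label_signs
    return x @ (classifier.training_features.T @ coeff) + classifier.bias


def predict(classifier: TrainedClassifier,
            features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and predicted class labels.

    A decision value of exactly 0 maps to the positive class.
    """
    decisions = decision_function(classifier, features)
    labels = np.where(decisions >= 0, classifier.positive_class,
                      classifier.negative_class)
    return decisions, labels


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             positive_class) -> FoldEvaluation:
    """Confusion counts and balanced accuracy with a stated positive class.

    Sensitivity refers to the positive (patient) class.  Raises if either
    class is absent from ``y_true`` (the corresponding rate is undefined).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    pos = y_true == positive_class
    if not pos.any() or pos.all():
        raise ValueError(
            "both classes must appear in the true labels to define "
            "sensitivity and specificity")
    pred_pos = y_pred == positive_class
    return FoldEvaluation(tp=int((pos & pred_pos).sum()),
                          tn=int((~pos & ~pred_pos).sum()),
                          fp=int((~pos & pred_pos).sum()),
                          fn=int((pos & ~pred_pos).sum()))


def covariate_stats(covariates: np.ndarray | pd.DataFrame
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Training-set mean and sd of each covariate column.

    Raises on missing values or zero-variance columns (cannot standardize).
    """
    c = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if c.ndim != 2:
        raise ValueError("covariates must be a 2D column block")
    if np.isnan(c).any():
        raise ValueError("covariates contain missing values")
    mean = c.mean(axis=0)
    sd = c.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"covariate column(s) {bad} have zero variance")
    return mean, sd


def augment_with_covariates(features: np.ndarray,
                            covariates: np.ndarray | pd.DataFrame,
                            mean: np.ndarray | None = None,
                            sd: np.ndarray | None = None) -> np.ndarray:
    """Append standardized covariate columns to a feature matrix.

    When ``mean``/``sd`` are given (training-set statistics) they are
    applied as-is — use this for test samples; otherwise the statistics
    are estimated from ``covariates`` itself.
    """
    x = np.asarray(features, dtype=np.float64)
    c = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if c.shape[0] != x.shape[0]:
        raise ValueError("covariate rows do not match feature rows")
    if np.isnan(c).any():
        raise ValueError("covariates contain missing values")
    if mean is None or sd is None:
        mean, sd = covariate_stats(c)
    return np.hstack([x, (c - mean) / sd])
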