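"""RBF-SVM classification, jackknife evaluation, and discriminant weights.

The classifier is a support vector machine with the radial basis function
kernel K(x, y) = exp(-gamma * ||x - y||^2); the default hyperparameters
C = 8192 (2^13) and gamma = 8.0 (2^3) are the grid-search optima for the
23-dimensional PseAAC representation on the DNA-binding benchmark this
package targets. Probabilities come from Platt-style sigmoid calibration of
the decision values (libsvm's internal calibration with a fixed seed).

Evaluation follows the conventions of the protein-classification literature:
leave-one-out ("jackknife") cross-validation and the confusion-matrix metrics
sensitivity, specificity, accuracy and Matthews correlation coefficient, plus
ROC/AUC over the continuous decision values.

The discriminant weight vector projects the trained model's signed dual
coefficients through the training feature matrix,

    W_j = sum_i A_i * M_ij,

so the sign of W_j indicates which class feature j favors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

DEFAULT_C = 8192.0
DEFAULT_GAMMA = 8.0

#: Power-of-two grids conventionally searched for (C, gamma); they contain
#: the package defaults 2^13 and 2^3.
DEFAULT_C_GRID = [2.0 ** e for e in range(-5, 16)]
DEFAULT_GAMMA_GRID = [2.0 ** e for e in range(-15, 4)]


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class EvalReport:
    """Confusion counts, threshold metrics (percent) and ROC summary."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Sensitivity, specificity, accuracy (percent) and MCC from counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero MCC denominator is reported as MCC = 0 with a warning.
    """
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented in the counts")
    total = tp + tn + fp + fn
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / total
    denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, sn=sn, sp=sp, acc=acc, mcc=float(mcc))


def counts_from_rates(
    sn_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int]:
    """Reconstruct (tp, tn, fp, fn) from printed Sn/Sp percentages.

    Finds the unique integer counts whose percentage matches the printed
    two-decimal value under either rounding or truncation (published tables
    use both conventions).
    """

    def match(count: int, n: int, printed: float) -> bool:
        pct = 100.0 * count / n
        return round(pct, 2) == printed or np.floor(pct * 100) / 100 == printed

    tps = [t for t in range(n_pos + 1) if match(t, n_pos, sn_pct)]
    tns = [t for t in range(n_neg + 1) if match(t, n_neg, sp_pct)]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"printed rates do not determine unique counts: "
            f"tp candidates {tps}, tn candidates {tns}"
        )
    tp, tn = tps[0], tns[0]
    return tp, tn, n_neg - tn, n_pos - tp


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) and AUC for continuous scores.

    AUC equals the Mann-Whitney U statistic normalized by n_pos * n_neg, with
    ties counted one half; constant scores therefore give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    pos_label = np.max(labels)
    y = (labels == pos_label).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


# ---------------------------------------------------------------------------
# Classifier


class ProfileSVM(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with calibrated probabilities and discriminant weights.

    A thin, deterministic wrapper around libsvm (via scikit-learn) that keeps
    the training matrix and exposes the signed dual coefficient of every
    training sample (zero for non-support samples), from which the
    discriminant weight vector W_j = sum_i A_i M_ij is computed.

    Parameters
    ----------
    C : float, default 8192
        Soft-margin penalty.
    gamma : float, default 8.0
        RBF kernel width.
    kernel : str, default "rbf"
        Passed through to libsvm; "linear" enables the closed-form
        cross-check of the discriminant weights against the primal vector.
    random_state : int, default 0
        Seed for the internal cross-validation of the Platt calibrator.
    """

    def __init__(
        self,
        C: float = DEFAULT_C,
        gamma: float = DEFAULT_GAMMA,
        kernel: str = "rbf",
        random_state: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {list(self.classes_)}"
            )
        with warnings.catch_warnings():
            # libsvm's built-in Platt calibration is the deliberate choice
            # here; sklearn 1.9 deprecates the flag in favor of
            # CalibratedClassifierCV, which fits a different calibrator.
            warnings.simplefilter("ignore", FutureWarning)
            self.svc_ = SVC(
                C=self.C,
                gamma=self.gamma,
                kernel=self.kernel,
                probability=True,
                random_state=self.random_state,
            )
            self.svc_.fit(X, y)
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        # libsvm's dual_coef_ covers support vectors only; scatter into a
        # full-length signed vector A (positive for the positive class).
        dual = np.zeros(X.shape[0])
        dual[self.svc_.support_] = self.svc_.dual_coef_[0]
        self.dual_coefficients_ = dual
        self.support_ = self.svc_.support_.copy()
        self.discriminant_weights_ = dual @ X
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(check_array(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.predict(check_array(X))

    def predict_proba(self, X) -> np.ndarray:
        """Platt-calibrated class probabilities, columns ordered as classes_."""
        check_is_fitted(self, "svc_")
        return self.svc_.predict_proba(check_array(X))


def train(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    random_state: int = 0,
) -> ProfileSVM:
    """Fit a :class:`ProfileSVM` on a feature matrix and +/-1 labels."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    return ProfileSVM(C=C, gamma=gamma, random_state=random_state).fit(
        features, labels
    )


def discriminant_weights(model: ProfileSVM) -> np.ndarray:
    """Per-feature discriminant weights W_j = sum_i A_i M_ij of a fitted model."""
    check_is_fitted(model, "discriminant_weights_")
    return model.discriminant_weights_.copy()


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: list[float] | None = None,
    gamma_grid: list[float] | None = None,
    folds: int = 5,
    random_state: int = 0,
) -> tuple[float, float]:
    """Pick (C, gamma) maximizing mean stratified-CV accuracy.

    Ties are broken toward smaller C, then smaller gamma, by scanning the
    grids in ascending order and requiring a strict improvement to switch.
    """
    C_grid = sorted(C_grid) if C_grid else DEFAULT_C_GRID
    gamma_grid = sorted(gamma_grid) if gamma_grid else DEFAULT_GAMMA_GRID
    if folds < 2:
        raise ValueError("folds must be >= 2")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] < folds:
        raise ValueError("fewer samples than folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for C in C_grid:
        for gamma in gamma_grid:
            svc = SVC(C=C, gamma=gamma, kernel="rbf")
            score = cross_val_score(svc, features, labels, cv=cv).mean()
            if score > best_score + 1e-12:
                best_score = score
                best = (C, gamma)
    assert best is not None
    return best


def jackknife(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> EvalReport:
    """Leave-one-out evaluation: each sample predicted by a model trained on
    the rest; counts, metrics and ROC/AUC accumulated over the N rounds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("jackknife requires at least 3 samples")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(
                f"class {c!r} has a single sample; holding it out would "
                "empty the class"
            )
    pos = np.max(classes)
    scores = np.empty(n)
    preds = np.empty(n, dtype=y.dtype)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(X[mask], y[mask])
        scores[i] = svc.decision_function(X[i : i + 1])[0]
        preds[i] = svc.predict(X[i : i + 1])[0]
        mask[i] = True
    tp = int(np.sum((preds == pos) & (y == pos)))
    tn = int(np.sum((preds != pos) & (y != pos)))
    fp = int(np.sum((preds == pos) & (y != pos)))
    fn = int(np.sum((preds != pos) & (y == pos)))
    report = metrics_from_counts(tp, tn, fp, fn)
    report.roc_points, report.auc = roc_auc(scores, y)
    return report


# ---------------------------------------------------------------------------
# Persistence

_MODEL_FORMAT = "psepro-model/1"


def save_model(
    model: ProfileSVM, path: str | Path, metadata: dict | None = None
) -> None:
    """Persist a fitted model as a versioned JSON archive.

    The archive stores hyperparameters, the training set and the fitted dual
    coefficients; loading refits the (deterministic) SVM on the stored
    training data, reconstructing the identical decision function.
    """
    check_is_fitted(model, "svc_")
    payload = {
        "format": _MODEL_FORMAT,
        "C": model.C,
        "gamma": model.gamma,
        "kernel": model.kernel,
        "random_state": model.random_state,
        "training_features": model.X_.tolist(),
        "labels": np.asarray(model.y_).tolist(),
        "dual_coefficients": model.dual_coefficients_.tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> ProfileSVM:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(
            f"{path}: unsupported model format {payload.get('format')!r}"
        )
    model = ProfileSVM(
        C=payload["C"],
        gamma=payload["gamma"],
        kernel=payload["kernel"],
        random_state=payload["random_state"],
    ).fit(np.array(payload["training_features"]), np.array(payload["labels"]))
    if not np.allclose(
        model.dual_coefficients_, payload["dual_coefficients"], atol=1e-6
    ):
        warnings.warn(f"{path}: refitted dual coefficients drifted from archive")
    return model
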