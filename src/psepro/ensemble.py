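"""Negative-pool partition ensemble.

Real proteomes contain far more non-DNA-binding than DNA-binding proteins.
To exploit a large negative pool without unbalancing any single classifier,
the pool is randomly partitioned into k roughly equal subsets, one SVM is
trained per subset paired with the shared positive set, and test samples are
scored by the arithmetic mean of the members' calibrated probabilities. The
predicted class is positive when the mean probability reaches 0.5 (exact
ties count as positive and are logged).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .model import DEFAULT_C, DEFAULT_GAMMA, ProfileSVM, load_model, save_model

logger = logging.getLogger(__name__)


def partition_negatives(
    neg_ids: list, k: int, seed: int
) -> list[list]:
    """Randomly split ids into k disjoint subsets of sizes differing by <= 1.

    A seeded uniform shuffle followed by round-robin slicing, so the split is
    reproducible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(neg_ids):
        raise ValueError(f"cannot split {len(neg_ids)} ids into {k} subsets")
    order = np.random.default_rng(seed).permutation(len(neg_ids))
    shuffled = [neg_ids[i] for i in order]
    return [shuffled[i::k] for i in range(k)]


class NegativePoolEnsemble(ClassifierMixin, BaseEstimator):
    """Probability-averaging ensemble over disjoint negative subsets.

    ``fit`` partitions the negative samples of the training set into
    ``n_members`` subsets and trains one :class:`ProfileSVM` per subset on
    that subset plus all positives. ``predict_proba`` averages the members'
    probabilities.

    Parameters
    ----------
    n_members : int, default 4
        Number of negative subsets / ensemble members.
    C, gamma : float
        Hyperparameters shared by every member.
    random_state : int, default 0
        Seed for the negative partition and the members' calibrators.
    """

    def __init__(
        self,
        n_members: int = 4,
        C: float = DEFAULT_C,
        gamma: float = DEFAULT_GAMMA,
        random_state: int = 0,
    ):
        self.n_members = n_members
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        pos_label = self.classes_[1]
        pos_idx = np.flatnonzero(y == pos_label)
        neg_idx = np.flatnonzero(y != pos_label)
        subsets = partition_negatives(
            neg_idx.tolist(), self.n_members, self.random_state
        )
        self.subset_assignments_ = {
            int(i): m for m, subset in enumerate(subsets) for i in subset
        }
        self.members_ = []
        for subset in subsets:
            idx = np.concatenate([pos_idx, np.array(subset, dtype=int)])
            member = ProfileSVM(
                C=self.C, gamma=self.gamma, random_state=self.random_state
            ).fit(X[idx], y[idx])
            self.members_.append(member)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        X = check_array(X)
        return np.mean([m.predict_proba(X) for m in self.members_], axis=0)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        ties = np.flatnonzero(proba == 0.5)
        if ties.size:
            logger.info(
                "%d sample(s) at mean probability exactly 0.5; "
                "assigned to the positive class", ties.size,
            )
        return np.where(proba >= 0.5, self.classes_[1], self.classes_[0])


def train_ensemble(
    pos_features: np.ndarray,
    neg_features_by_subset: list[np.ndarray],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    random_state: int = 0,
) -> NegativePoolEnsemble:
    """Build a fitted ensemble from a pre-partitioned negative pool.

    Member i is trained on the positives plus negative subset i; labels are
    +1 for positives, -1 for negatives.
    """
    if not neg_features_by_subset:
        raise ValueError("at least one negative subset required")
    for i, sub in enumerate(neg_features_by_subset):
        if len(sub) == 0:
            raise ValueError(f"negative subset {i} is empty")
    ens = NegativePoolEnsemble(
        n_members=len(neg_features_by_subset),
        C=C,
        gamma=gamma,
        random_state=random_state,
    )
    ens.classes_ = np.array([-1, 1])
    ens.members_ = []
    ens.subset_assignments_ = {}
    pos = np.asarray(pos_features, dtype=float)
    offset = 0
    for m, sub in enumerate(neg_features_by_subset):
        sub = np.asarray(sub, dtype=float)
        X = np.vstack([pos, sub])
        y = np.concatenate([np.ones(len(pos)), -np.ones(len(sub))])
        ens.members_.append(
            ProfileSVM(C=C, gamma=gamma, random_state=random_state).fit(X, y)
        )
        for i in range(len(sub)):
            ens.subset_assignments_[offset + i] = m
        offset += len(sub)
    ens.n_features_in_ = pos.shape[1]
    return ens


def predict_ensemble(
    model: NegativePoolEnsemble, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean positive-class probabilities and predicted labels."""
    proba = model.predict_proba(features)[:, 1]
    labels = model.predict(features)
    return proba, labels


# ---------------------------------------------------------------------------
# Persistence: a manifest referencing member archives

_ENSEMBLE_FORMAT = "psepro-ensemble/1"


def save_ensemble(
    model: NegativePoolEnsemble, path: str | Path, metadata: dict | None = None
) -> None:
    check_is_fitted(model, "members_")
    path = Path(path)
    member_paths = []
    for i, member in enumerate(model.members_):
        mpath = path.with_suffix(f".member{i}.json")
        save_model(member, mpath)
        member_paths.append(mpath.name)
    manifest = {
        "format": _ENSEMBLE_FORMAT,
        "n_members": len(model.members_),
        "C": model.C,
        "gamma": model.gamma,
        "partition_seed": model.random_state,
        "subset_assignments": {
            str(k): v for k, v in model.subset_assignments_.items()
        },
        "classes": np.asarray(model.classes_).tolist(),
        "members": member_paths,
        "metadata": metadata or {},
    }
    path.write_text(json.dumps(manifest) + "\n")


def load_ensemble(path: str | Path) -> NegativePoolEnsemble:
    path = Path(path)
    manifest = json.loads(path.read_text())
    if manifest.get("format") != _ENSEMBLE_FORMAT:
        raise ValueError(f"{path}: unsupported ensemble format")
    ens = NegativePoolEnsemble(
        n_members=manifest["n_members"],
        C=manifest["C"],
        gamma=manifest["gamma"],
        random_state=manifest["partition_seed"],
    )
    ens.members_ = [load_model(path.parent / m) for m in manifest["members"]]
    ens.subset_assignments_ = {
        int(k): v for k, v in manifest["subset_assignments"].items()
    }
    ens.classes_ = np.array(manifest["classes"])
    ens.n_features_in_ = ens.members_[0].n_features_in_
    return ens
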