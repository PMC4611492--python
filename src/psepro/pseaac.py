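"""Pseudo amino acid composition (PseAAC) feature extraction.

A sequence (typically the profile consensus P') of length L is converted into
a fixed-length vector of 20 + lambda entries: the 20 relative residue
frequencies f_u followed by lambda sequence-order correlation factors
theta_k, each down-weighted by omega and jointly normalized so the vector
sums to 1:

    x_u = f_u / D                    for u = 1..20
    x_u = omega * theta_{u-20} / D   for u = 21..20+lambda
    D   = sum_v f_v + omega * sum_k theta_k

The correlation factor at lag k averages the physicochemical dissimilarity
Theta(R_i, R_{i+k}) over all residue pairs k positions apart, where Theta is
the mean squared difference of the z-scored property values:

    theta_k = (1 / (L - k)) * sum_{i=1}^{L-k} Theta(R_i, R_{i+k})
    Theta(a, b) = (1 / n_props) * sum_j (H_j(a) - H_j(b))^2

With the defaults lambda = 3 and omega = 0.7 the feature vector has 23
entries.

The module exposes the individual operations and a scikit-learn transformer,
:class:`PseaacEncoder`, that maps lists of sequences to feature matrices and
composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .alphabet import AA_INDEX, AMINO_ACIDS
from .profiles import ProfileSequence, Sequence
from .properties import PropertyTable, default_property_table

DEFAULT_LAMBDA = 3
DEFAULT_OMEGA = 0.7


@dataclass(frozen=True)
class PseaacVector:
    """One (20 + lambda)-dimensional PseAAC feature vector."""

    seq_id: str
    lam: int
    omega: float
    values: np.ndarray
    theta: np.ndarray
    comp: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (20 + self.lam,):
            raise ValueError("values must have length 20 + lambda")
        if np.any(self.values < 0) or abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("values must be nonnegative and sum to 1")


def _residues_of(p: ProfileSequence | Sequence | str) -> tuple[str, str]:
    if isinstance(p, (ProfileSequence, Sequence)):
        return p.seq_id if isinstance(p, ProfileSequence) else p.id, p.residues
    return "", str(p)


def _pairwise_theta_matrix(props: PropertyTable) -> np.ndarray:
    """20x20 matrix of Theta(a, b) for every residue pair."""
    H = props.normalized  # (n_props, 20)
    diff = H[:, :, None] - H[:, None, :]
    return (diff ** 2).mean(axis=0)


def theta_pair(a: str, b: str, props: PropertyTable | None = None) -> float:
    """Mean squared normalized-property difference between two residues."""
    props = props if props is not None else default_property_table()
    for r in (a, b):
        if r not in AA_INDEX:
            raise ValueError(f"non-standard residue {r!r}")
    H = props.normalized
    return float(((H[:, AA_INDEX[a]] - H[:, AA_INDEX[b]]) ** 2).mean())


def correlation_factors(
    p: ProfileSequence | Sequence | str,
    lam: int,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Sequence-order correlation factors theta_1 .. theta_lambda."""
    props = props if props is not None else default_property_table()
    seq_id, residues = _residues_of(p)
    L = len(residues)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam >= L:
        raise ValueError(
            f"lambda={lam} requires sequence length > {lam}, but "
            f"{seq_id or 'sequence'!r} has length {L}; lower lambda or drop "
            "the sequence"
        )
    theta_mat = _pairwise_theta_matrix(props)
    try:
        idx = np.array([AA_INDEX[r] for r in residues])
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {seq_id!r}")
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        theta[k - 1] = theta_mat[idx[:-k], idx[k:]].mean()
    return theta


def pseaac_features(
    p: ProfileSequence | Sequence | str,
    lam: int = DEFAULT_LAMBDA,
    omega: float = DEFAULT_OMEGA,
    props: PropertyTable | None = None,
) -> PseaacVector:
    """The (20 + lambda)-dimensional PseAAC vector of one sequence."""
    props = props if props is not None else default_property_table()
    if omega <= 0:
        raise ValueError("omega must be positive")
    seq_id, residues = _residues_of(p)
    theta = correlation_factors(p, lam, props)
    idx = np.array([AA_INDEX[r] for r in residues])
    comp = np.bincount(idx, minlength=20).astype(float) / len(residues)
    denom = comp.sum() + omega * theta.sum()
    values = np.concatenate([comp, omega * theta]) / denom
    return PseaacVector(
        seq_id=seq_id, lam=lam, omega=omega, values=values, theta=theta, comp=comp
    )


def featurize_batch(
    items: list[ProfileSequence | Sequence | str],
    lam: int = DEFAULT_LAMBDA,
    omega: float = DEFAULT_OMEGA,
    props: PropertyTable | None = None,
    permissive: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for a batch; rows follow input order.

    Items violating the ``lambda < L`` precondition raise a ``ValueError``
    listing the offending ids unless ``permissive`` is set, in which case they
    are dropped (and absent from the returned id list).
    """
    props = props if props is not None else default_property_table()
    rows, ids, failures = [], [], []
    for item in items:
        try:
            vec = pseaac_features(item, lam, omega, props)
        except ValueError:
            failures.append(_residues_of(item)[0])
            continue
        rows.append(vec.values)
        ids.append(vec.seq_id)
    if failures and not permissive:
        raise ValueError(
            f"{len(failures)} item(s) failed feature extraction at "
            f"lambda={lam}: {failures}"
        )
    matrix = np.vstack(rows) if rows else np.empty((0, 20 + lam))
    return matrix, ids


def feature_names(lam: int = DEFAULT_LAMBDA) -> list[str]:
    """Column labels: the 20 residues then the lag factors."""
    return list(AMINO_ACIDS) + [f"theta_{k}" for k in range(1, lam + 1)]


class PseaacEncoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from sequences to PseAAC feature matrices.

    Parameters
    ----------
    lam : int, default 3
        Number of sequence-order correlation factors (the distance parameter).
    omega : float, default 0.7
        Weight of the sequence-order factors relative to composition.
    property_table : PropertyTable or None
        Physicochemical panel; the packaged seven-property default when None.
    permissive : bool, default False
        Drop sequences shorter than ``lam + 1`` instead of raising.
    """

    def __init__(
        self,
        lam: int = DEFAULT_LAMBDA,
        omega: float = DEFAULT_OMEGA,
        property_table: PropertyTable | None = None,
        permissive: bool = False,
    ):
        self.lam = lam
        self.omega = omega
        self.property_table = property_table
        self.permissive = permissive

    def fit(self, X, y=None):  # noqa: D102 - stateless, sklearn protocol
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 < self.omega:
            raise ValueError("omega must be positive")
        self.n_features_out_ = 20 + self.lam
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        matrix, _ = featurize_batch(
            list(X), self.lam, self.omega, self.property_table, self.permissive
        )
        return matrix

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_features_out_")
        return np.asarray(feature_names(self.lam), dtype=object)
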