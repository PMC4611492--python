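"""Independent reference implementations used as test oracles.

These are deliberately naive (explicit loops, no shared code with the
package's vectorized paths) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def naive_theta_pair(a: str, b: str, normalized: np.ndarray) -> float:
    """Mean squared difference over property rows, by explicit loop."""
    n_props = normalized.shape[0]
    total = 0.0
    for j in range(n_props):
        d = normalized[j, AA.index(a)] - normalized[j, AA.index(b)]
        total += d * d
    return total / n_props


def naive_pseaac(
    residues: str, lam: int, omega: float, normalized: np.ndarray
) -> np.ndarray:
    """PseAAC vector straight from the defining equations."""
    L = len(residues)
    theta = []
    for k in range(1, lam + 1):
        acc = 0.0
        for i in range(L - k):
            acc += naive_theta_pair(residues[i], residues[i + k], normalized)
        theta.append(acc / (L - k))
    freqs = [residues.count(a) / L for a in AA]
    denom = sum(freqs) + omega * sum(theta)
    return np.array(
        [f / denom for f in freqs] + [omega * t / denom for t in theta]
    )


def naive_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise O(n^2) Mann-Whitney AUC with ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == max(labels)]
    neg = [s for s, y in zip(scores, labels) if y != max(labels)]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_loo_counts(X, y, C, gamma):
    """Leave-one-out confusion counts and decision scores via a fresh loop."""
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    pos = max(np.unique(y))
    tp = tn = fp = fn = 0
    scores = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(X[keep], y[keep])
        pred = clf.predict(X[i : i + 1])[0]
        scores.append(clf.decision_function(X[i : i + 1])[0])
        if y[i] == pos:
            tp += pred == pos
            fn += pred != pos
        else:
            tn += pred != pos
            fp += pred == pos
    return (int(tp), int(tn), int(fp), int(fn)), np.array(scores)
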