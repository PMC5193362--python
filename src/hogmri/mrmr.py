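"""Minimum-redundancy-maximum-relevance (mRMR) greedy feature ranking.

mRMR ranks features by mutual information (MI) with the class label
while penalising MI with the features already selected.  The difference
("MID") criterion is the default: after the first pick (maximum
relevance), each subsequent pick maximises

    MI(f, y) - (1/|S|) * sum_{s in S} MI(f, s)

over the unselected features f, S being the selected set.  The quotient
("MIQ") form divides instead of subtracting.  MI is the plug-in
estimate from the empirical joint distribution, in bits; continuous
features are first discretised into three states at mean +/- SD, the
scheme of the original mRMR software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Symmetric, non-negative, and bounded by min(H(x), H(y)).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError(f"need two equal-length 1-D vectors, got {x.shape} and {y.shape}")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    hxy = _entropy_from_counts(joint.ravel())
    return max(0.0, hx + hy - hxy)


def _mi_many(X: np.ndarray, y: np.ndarray, n_states: np.ndarray, ny: int) -> np.ndarray:
    """MI of every column of integer-coded X with integer-coded y (vectorised)."""
    n, d = X.shape
    out = np.empty(d)
    # group rows by y once; per column a bincount over codes gives the joint
    hy = _entropy_from_counts(np.bincount(y, minlength=ny))
    for j in range(d):
        k = int(n_states[j])
        joint = np.bincount(X[:, j] * ny + y, minlength=k * ny).reshape(k, ny)
        hx = _entropy_from_counts(joint.sum(axis=1))
        hxy = _entropy_from_counts(joint.ravel())
        out[j] = max(0.0, hx + hy - hxy)
    return out


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedMatrix:
    """Integer-coded feature matrix ready for MI computation.

    ``values[i, j]`` is the state code of subject i on feature j, in
    ``[0, n_states_per_feature[j])``.
    """

    values: np.ndarray              # (n_subjects, n_features) int
    n_states_per_feature: np.ndarray
    scheme: str = "mean_sd_3"

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def discretize(X, categorical=None) -> DiscretizedMatrix:
    """Discretise continuous columns into 3 states at mean +/- SD.

    Codes: 0 for values <= mean - SD, 2 for values >= mean + SD, 1
    between (sample SD, ddof=1).  A constant column collapses to the
    single state 0 (its MI with anything is then 0).  Columns flagged in
    ``categorical`` — or detected as already integer-coded with at most
    3 distinct values — are passed through unchanged, re-coded to
    0..m-1.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("discretize requires finite values")
    n, d = X.shape
    if categorical is None:
        categorical = np.zeros(d, dtype=bool)
    categorical = np.asarray(categorical, dtype=bool)
    codes = np.empty((n, d), dtype=np.int64)
    n_states = np.empty(d, dtype=np.int64)
    for j in range(d):
        col = X[:, j]
        uniq = np.unique(col)
        is_cat = categorical[j] or (uniq.size <= 3 and np.all(uniq == np.round(uniq)))
        if uniq.size == 1:
            codes[:, j] = 0
            n_states[j] = 1
        elif is_cat:
            codes[:, j] = np.searchsorted(uniq, col)
            n_states[j] = uniq.size
        else:
            mu = col.mean()
            sd = col.std(ddof=1)
            c = np.ones(n, dtype=np.int64)
            c[col <= mu - sd] = 0
            c[col >= mu + sd] = 2
            codes[:, j] = c
            n_states[j] = 3
    return DiscretizedMatrix(codes, n_states)


# ---------------------------------------------------------------------------
# Greedy selection
# ---------------------------------------------------------------------------

@dataclass
class MRMRRanking:
    """Ordered feature indices with the per-step selection scores."""

    order: list[int]
    scores: list[float]

    def top(self, k: int) -> list[int]:
        return self.order[:k]


def mrmr_select(X: DiscretizedMatrix, y, k: int, variant: str = "MID") -> MRMRRanking:
    """Greedy mRMR ranking of the first ``k`` features.

    The first pick maximises MI with the label; each later pick
    maximises relevance minus mean redundancy (MID) or relevance over
    mean redundancy (MIQ).  Ties break to the lowest feature index,
    making the ranking deterministic.
    """
    if variant not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR variant {variant!r}")
    y = np.asarray(y)
    codes = X.values
    n, d = codes.shape
    if y.shape != (n,):
        raise ValueError(f"labels shape {y.shape} does not match {n} subjects")
    if not 1 <= k <= d:
        raise ValueError(f"k={k} out of range [1, {d}]")
    _, yi = np.unique(y, return_inverse=True)
    ny = int(yi.max()) + 1
    relevance = _mi_many(codes, yi, X.n_states_per_feature, ny)

    order: list[int] = []
    scores: list[float] = []
    selected = np.zeros(d, dtype=bool)
    redundancy_sum = np.zeros(d)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            mean_red = redundancy_sum / step
            if variant == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / (mean_red + 1e-12)
        crit[selected] = -np.inf
        pick = int(np.argmax(crit))  # argmax takes the lowest index on ties
        order.append(pick)
        scores.append(float(crit[pick]))
        selected[pick] = True
        if step < k - 1:
            s = codes[:, pick]
            ns = int(X.n_states_per_feature[pick])
            redundancy_sum += _mi_many(codes, s, X.n_states_per_feature, ns)
    return MRMRRanking(order, scores)
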