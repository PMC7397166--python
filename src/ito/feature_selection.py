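"""Mutual-information filter feature selection: mRMR, JMI and JMIM.

Continuous expression values are discretized by equal-frequency binning
(rank order split into ``n_bins`` chunks; tied values always share a bin),
and mutual information is estimated with the plug-in (maximum likelihood)
estimator on the observed contingency table, in nats.

All three criteria are greedy forward selections over the discretized
features X_j against the binary label Y. The first pick is always
argmax I(X;Y); thereafter, with S the selected set:

mRMR   argmax  I(X;Y) - (1/|S|) * sum_{s in S} I(X;X_s)      (difference form)
JMI    argmax  sum_{s in S} I((X,X_s);Y)
JMIM   argmax  min_{s in S} I((X,X_s);Y)

Joint variables (X,X_s) live on the product alphabet of the two bin codes.
Selection is fully deterministic; score ties — detected within a small
numerical tolerance, since equal contingency tables can sum to values a
few ulp apart — go to the lower feature index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

FSS_METHODS = ("jmi", "jmim", "mrmr")


class SelectionError(ValueError):
    pass


@dataclass
class DiscretizedFeature:
    """Equal-frequency bin codes for one feature."""

    codes: np.ndarray  # int, 0..n_bins-1
    n_bins: int
    feature_id: str | None = None


@dataclass
class SelectionResult:
    """Ordered greedy selection with the criterion score at each step."""

    feature_ids: list
    scores: list
    method: str
    n_bins: int


def discretize(values, n_bins: int, feature_id: str | None = None) -> DiscretizedFeature:
    """Equal-frequency binning on rank order; equal values share a bin.

    A constant vector maps to all-zero codes. ``n_bins`` larger than the
    sample count is clamped (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise SelectionError("cannot discretize missing values")
    if n_bins < 2:
        raise SelectionError("n_bins must be >= 2")
    n = len(values)
    if n_bins > n:
        warnings.warn(f"n_bins={n_bins} > n_samples={n}; clamping", stacklevel=2)
        n_bins = n
    ranks = rankdata(values, method="min").astype(np.int64) - 1
    codes = (ranks * n_bins) // n
    return DiscretizedFeature(codes=codes.astype(np.int64), n_bins=n_bins, feature_id=feature_id)


#: scores closer than this are a tie (resolved to the lower feature index)
_TIE_TOL = 1e-10


def _argmax_stable(scores: np.ndarray) -> int:
    top = scores.max()
    return int(np.flatnonzero(scores >= top - _TIE_TOL)[0])


def _mi_codes(a: np.ndarray, na: int, b: np.ndarray, nb: int) -> float:
    """Plug-in mutual information (nats) between two integer code vectors."""
    counts = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    n = counts.sum()
    pij = counts / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    outer = np.outer(pi, pj)
    val = float(np.sum(pij[nz] * (np.log(pij[nz]) - np.log(outer[nz]))))
    return max(val, 0.0)


def mutual_information(a, b) -> float:
    """I(A;B) in nats from two equal-length discrete vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise SelectionError("vectors must be 1-d and of equal length")
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    return _mi_codes(ca.astype(np.int64), int(ca.max()) + 1, cb.astype(np.int64), int(cb.max()) + 1)


def select_features(data, method: str, k: int, n_bins: int = 5) -> SelectionResult:
    """Greedy forward selection of ``k`` features from a clean dataset.

    ``data`` must have missing features excluded already; its binary labels
    are the selection target. ``method`` is one of ``mrmr``/``jmi``/``jmim``
    (case-insensitive).
    """
    method = method.lower()
    if method not in FSS_METHODS:
        raise SelectionError(f"unknown FSS method {method!r}")
    if k <= 0:
        raise SelectionError("k must be positive")
    if k > data.n_features:
        raise SelectionError(f"k={k} exceeds the {data.n_features} available features")
    if np.isnan(data.matrix).any():
        raise SelectionError("dataset contains missing values; exclude them first")

    n, f = data.matrix.shape
    y = data.labels.astype(np.int64)
    codes = np.empty((n, f), dtype=np.int64)
    levels = np.empty(f, dtype=np.int64)
    for j in range(f):
        d = discretize(data.matrix[:, j], n_bins)
        codes[:, j] = d.codes
        levels[j] = d.n_bins

    relevance = np.array([_mi_codes(codes[:, j], levels[j], y, 2) for j in range(f)])
    selected: list[int] = []
    scores: list[float] = []
    chosen = np.zeros(f, dtype=bool)
    red_sum = np.zeros(f)
    jmi_sum = np.zeros(f)
    jmi_min = np.full(f, np.inf)

    first = _argmax_stable(relevance)
    selected.append(first)
    chosen[first] = True
    scores.append(float(relevance[first]))

    while len(selected) < k:
        s = selected[-1]
        for j in np.flatnonzero(~chosen):
            if method == "mrmr":
                red_sum[j] += _mi_codes(codes[:, j], levels[j], codes[:, s], levels[s])
            else:
                joint = codes[:, j] * levels[s] + codes[:, s]
                t = _mi_codes(joint, levels[j] * levels[s], y, 2)
                jmi_sum[j] += t
                jmi_min[j] = min(jmi_min[j], t)
        if method == "mrmr":
            crit = relevance - red_sum / len(selected)
        elif method == "jmi":
            crit = jmi_sum.copy()
        else:
            crit = jmi_min.copy()
        crit[chosen] = -np.inf
        nxt = _argmax_stable(crit)
        selected.append(nxt)
        chosen[nxt] = True
        scores.append(float(crit[nxt]))

    return SelectionResult(
        feature_ids=[data.feature_ids[j] for j in selected],
        scores=scores,
        method=method,
        n_bins=n_bins,
    )
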