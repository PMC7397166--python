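"""Missing-feature exclusion and train-fitted per-feature scaling.

The preprocessing stage drops every feature that has at least one missing
value in the *training* set (features are abundant; a feature with holes
under-represents the sample space), then scales with one of three methods
fitted on training data only:

``standard``  (x - mean) / sd
``robust``    (x - median) / IQR
``quantile``  empirical CDF of the training values, (rank - 0.5)/n with
              averaged ranks for ties, mapping into [0, 1]
``none``      identity

Features that are constant on the training set (zero sd or zero IQR)
transform to exactly 0 (0.5 under quantile — the averaged rank of a single
tied group). Scalers are bound to the feature ids they were fitted on and
refuse to transform anything else. Validation-side missing values that
survive exclusion are imputed with the training median.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

SCALER_METHODS = ("none", "quantile", "robust", "standard")


class PreprocessingError(ValueError):
    pass


@dataclass
class FittedScaler:
    """Per-feature scaling parameters estimated from a training set."""

    method: str
    feature_ids: list
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    # per-feature sorted unique training values and their ECDF levels
    quantile_values: list = field(default_factory=list)
    quantile_cdf: list = field(default_factory=list)

    def subset(self, ids) -> "FittedScaler":
        """Restrict the fit to a subset of its bound features (kept order = ids)."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            idx = [pos[str(f)] for f in ids]
        except KeyError as exc:
            raise PreprocessingError(f"scaler not fitted for feature {exc.args[0]!r}") from None
        return FittedScaler(
            method=self.method,
            feature_ids=[str(f) for f in ids],
            center=None if self.center is None else self.center[idx],
            scale=None if self.scale is None else self.scale[idx],
            quantile_values=[self.quantile_values[i] for i in idx] if self.quantile_values else [],
            quantile_cdf=[self.quantile_cdf[i] for i in idx] if self.quantile_cdf else [],
        )


def exclude_missing_features(train, others=()):
    """Drop features with any missing training value; impute the rest.

    Every feature with >= 1 missing cell in ``train`` is removed from
    ``train`` and from every dataset in ``others`` (which must share the
    training feature ids in order). Residual missing cells in ``others``
    within surviving features are filled with the training median.

    Returns ``(train', others', kept_feature_ids)``.
    """
    from .dataset_io import ExpressionDataset

    for o in others:
        if o.feature_ids != train.feature_ids:
            raise PreprocessingError("datasets must share identical feature ids in order")
    keep = ~np.isnan(train.matrix).any(axis=0)
    if not keep.any():
        raise PreprocessingError("no features survive missing-value exclusion")
    kept_ids = [f for f, k in zip(train.feature_ids, keep) if k]
    new_train = ExpressionDataset(
        train.matrix[:, keep].copy(), train.labels.copy(), list(train.sample_ids), kept_ids
    )
    medians = np.median(new_train.matrix, axis=0)
    new_others = []
    for o in others:
        m = o.matrix[:, keep].copy()
        holes = np.isnan(m)
        if holes.any():
            m[holes] = np.broadcast_to(medians, m.shape)[holes]
        new_others.append(
            ExpressionDataset(m, o.labels.copy(), list(o.sample_ids), list(kept_ids))
        )
    return new_train, new_others, kept_ids


def fit_scaler(train, method: str) -> FittedScaler:
    """Fit scaling parameters on a training set with no missing values."""
    if method not in SCALER_METHODS:
        raise PreprocessingError(f"unknown scaling method {method!r}")
    X = train.matrix
    if np.isnan(X).any():
        raise PreprocessingError("training data must have missing features excluded first")
    scaler = FittedScaler(method=method, feature_ids=list(train.feature_ids))
    if method == "standard":
        scaler.center = X.mean(axis=0)
        scaler.scale = X.std(axis=0)
    elif method == "robust":
        q25, q50, q75 = np.percentile(X, [25, 50, 75], axis=0)
        scaler.center = q50
        scaler.scale = q75 - q25
    elif method == "quantile":
        n = X.shape[0]
        for j in range(X.shape[1]):
            col = X[:, j]
            levels = (rankdata(col, method="average") - 0.5) / n
            uq, inv = np.unique(col, return_inverse=True)
            lev = np.empty(len(uq))
            lev[inv] = levels  # equal values share an averaged rank
            scaler.quantile_values.append(uq)
            scaler.quantile_cdf.append(lev)
    return scaler


def transform_matrix(scaler: FittedScaler, X: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler to a raw value matrix (columns = bound features)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(scaler.feature_ids):
        raise PreprocessingError("matrix width does not match the scaler's bound features")
    if scaler.method == "none":
        return X.copy()
    if scaler.method == "quantile":
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            out[:, j] = np.interp(
                X[:, j], scaler.quantile_values[j], scaler.quantile_cdf[j], left=0.0, right=1.0
            )
        return out
    degenerate = scaler.scale == 0
    safe = np.where(degenerate, 1.0, scaler.scale)
    out = (X - scaler.center) / safe
    out[:, degenerate] = 0.0
    return out


def apply_scaler(scaler: FittedScaler, data):
    """Transform a dataset whose feature ids equal the scaler's bound ids."""
    from .dataset_io import ExpressionDataset

    if data.feature_ids != scaler.feature_ids:
        raise PreprocessingError("dataset features do not match the scaler's bound features")
    return ExpressionDataset(
        transform_matrix(scaler, data.matrix),
        data.labels.copy(),
        list(data.sample_ids),
        list(data.feature_ids),
    )
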