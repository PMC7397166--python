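"""Attack-vector grid and the training of LIG and FT base classifiers.

A *soldier* is one base classifier trained under one *attack vector* — a
4-tuple (preprocessing, FSS method, subset size, validation method) drawn
from the Cartesian option grid. Each soldier runs its own pipeline:

    exclude missing features -> fit/apply scaler -> MI feature selection
    -> classifier

and is scored by pooled out-of-fold predictions on the training set under
its own validation method (stratified 10-fold CV or LOOCV), yielding the
selection-time accuracy, MCC and rho used for filtering and ensembling.

LIG (lightweight infantry group) soldiers are parameter-free classifiers
at library defaults; FT (follow-up team) soldiers grid-search a parameter
space and keep the assignment with the best selection rho (ties: higher
MCC, then first seen). Scaling and feature selection are fit once on the
whole training set per attack vector; only the classifier is refit per CV
fold. Nothing in the pipeline ever sees holdout data.
"""
from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import select_features
from .metrics import EvaluationResult
from .preprocessing import (
    FittedScaler,
    apply_scaler,
    exclude_missing_features,
    fit_scaler,
    transform_matrix,
)

VALIDATIONS = ("loocv", "tenfold_cv")


class SoldierError(ValueError):
    pass


def derive_seed(master: int, *keys) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and context keys."""
    entropy = [int(master) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class AttackVector:
    """One pipeline configuration tuple from the option grid."""

    prep: str
    fss_method: str
    subset_size: int
    validation: str

    def to_dict(self) -> dict:
        return {
            "prep": self.prep,
            "fss_method": self.fss_method,
            "subset_size": self.subset_size,
            "validation": self.validation,
        }


def generate_options_grid(preps, sizes, fss_methods, validations) -> list:
    """Full Cartesian product in deterministic lexicographic order."""
    dims = {
        "preps": sorted(set(preps)),
        "sizes": sorted(set(int(s) for s in sizes)),
        "fss_methods": sorted(set(fss_methods)),
        "validations": sorted(set(validations)),
    }
    for name, vals in dims.items():
        if not vals:
            raise SoldierError(f"option set {name!r} is empty")
    return [
        AttackVector(prep=p, fss_method=m, subset_size=s, validation=v)
        for p in dims["preps"]
        for m in dims["fss_methods"]
        for s in dims["sizes"]
        for v in dims["validations"]
    ]


def sample_grid(grid, fraction: float, seed: int) -> list:
    """Uniform sample without replacement of floor(fraction*|G|) vectors (min 1)."""
    if not 0 < fraction <= 1:
        raise SoldierError("fraction must be in (0, 1]")
    m = max(1, int(fraction * len(grid)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=m, replace=False)
    return [grid[i] for i in idx]


# ---------------------------------------------------------------------------
# classifier registries
# ---------------------------------------------------------------------------
# Families are pluggable by contract: anything providing sklearn-style
# fit(X, y)/predict(X) on numeric matrices qualifies.

LIG_FAMILIES = {
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "extra_trees": lambda seed: ExtraTreesClassifier(random_state=seed),
}

# FT parameter grids: the published tuning spaces for the three
# parameterized families (MLP hidden-layer specs read as 1/2/3 hidden
# layers of width 100).
DEFAULT_FT_GRIDS = {
    "mlp": {
        "learning_rate": ["constant", "invscaling", "adaptive"],
        "alpha": [1, 0.1, 0.001, 0.0001, 1e-05, 1e-06, 1e-07, 1e-08],
        "activation": ["logistic", "relu", "tanh"],
        "hidden_layer_sizes": [(100,), (100, 100), (100, 100, 100)],
    },
    "svm": {
        "C": [0.001, 0.01, 0.1, 1, 10],
        "gamma": [0.001, 0.01, 0.1, 1],
        "kernel": ["rbf", "linear"],
    },
    "random_forest": {
        "n_estimators": [100, 300, 500, 800, 1000],
        "criterion": ["gini", "entropy"],
        "bootstrap": [True, False],
    },
}

FT_FAMILIES = {
    "mlp": lambda params, seed: MLPClassifier(random_state=seed, **params),
    "svm": lambda params, seed: SVC(random_state=seed, **params),
    "random_forest": lambda params, seed: RandomForestClassifier(random_state=seed, **params),
}


def register_lig_family(name: str, factory) -> None:
    """Register a parameter-free family: ``factory(seed) -> estimator``."""
    LIG_FAMILIES[name] = factory


def register_ft_family(name: str, factory, default_grid: dict) -> None:
    """Register a parameterized family: ``factory(params, seed) -> estimator``."""
    FT_FAMILIES[name] = factory
    DEFAULT_FT_GRIDS[name] = default_grid


@dataclass(eq=False)
class Soldier:
    """A trained base classifier with its pipeline state and evaluations."""

    phase: str  # "LIG" | "FT"
    classifier_family: str
    attack_vector: AttackVector
    best_params: dict
    selected_feature_ids: list
    scaler: FittedScaler  # restricted to the selected features
    impute_values: np.ndarray  # training medians of the selected features
    classifier: object  # fitted on the full training set
    selection_eval: EvaluationResult
    selection_predictions: np.ndarray  # pooled out-of-fold training predictions
    seed: int
    holdout_eval: EvaluationResult | None = None

    def predict(self, dataset) -> np.ndarray:
        """Predict labels for a dataset alignable to the selected features."""
        idx = dataset.feature_index(self.selected_feature_ids)
        X = dataset.matrix[:, idx].copy()
        holes = np.isnan(X)
        if holes.any():
            X[holes] = np.broadcast_to(self.impute_values, X.shape)[holes]
        X = transform_matrix(self.scaler, X)
        return np.asarray(self.classifier.predict(X), dtype=int)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "classifier_family": self.classifier_family,
            "attack_vector": self.attack_vector.to_dict(),
            "best_params": {k: _jsonable(v) for k, v in self.best_params.items()},
            "selected_feature_ids": list(self.selected_feature_ids),
            "seed": self.seed,
            "selection": self.selection_eval.to_dict(),
            "holdout": None if self.holdout_eval is None else self.holdout_eval.to_dict(),
        }


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _prepare_pipeline(train, av: AttackVector, n_bins: int):
    """Fit the per-attack-vector pipeline on training data only."""
    if len(np.unique(train.labels)) < 2:
        raise SoldierError("training data must contain both classes")
    clean, _, _ = exclude_missing_features(train, [])
    scaler = fit_scaler(clean, av.prep)
    scaled = apply_scaler(scaler, clean)
    k = av.subset_size
    if k > scaled.n_features:
        warnings.warn(
            f"subset_size={k} exceeds {scaled.n_features} surviving features; clamping",
            stacklevel=3,
        )
        k = scaled.n_features
    sel = select_features(scaled, av.fss_method, k, n_bins=n_bins)
    cols = scaled.feature_index(sel.feature_ids)
    X = scaled.matrix[:, cols]
    medians = np.median(clean.matrix[:, cols], axis=0)
    return X, sel.feature_ids, scaler.subset(sel.feature_ids), medians


def _oof_predictions(X: np.ndarray, y: np.ndarray, validation: str, prototype) -> np.ndarray:
    """Pooled out-of-fold predictions under the soldier's validation method."""
    if validation == "loocv":
        splits = LeaveOneOut().split(X, y)
    elif validation == "tenfold_cv":
        n_splits = min(10, int(np.bincount(y).min()))
        if n_splits < 2:
            raise SoldierError("too few samples per class for stratified CV")
        splits = StratifiedKFold(n_splits=n_splits).split(X, y)
    else:
        raise SoldierError(f"unknown validation method {validation!r}")
    pred = np.empty(len(y), dtype=int)
    for tr, te in splits:
        clf = clone(prototype)
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
    return pred


def train_lig_soldier(train, av: AttackVector, family: str, seed: int, n_bins: int = 5) -> Soldier:
    """Train one parameter-free soldier under an attack vector."""
    if family not in LIG_FAMILIES:
        raise SoldierError(f"unknown LIG family {family!r}")
    X, feat_ids, scaler, medians = _prepare_pipeline(train, av, n_bins)
    y = train.labels
    prototype = LIG_FAMILIES[family](seed)
    oof = _oof_predictions(X, y, av.validation, prototype)
    sel_eval = EvaluationResult.from_predictions(oof, y)
    final = clone(prototype)
    final.fit(X, y)
    return Soldier(
        phase="LIG",
        classifier_family=family,
        attack_vector=av,
        best_params={},
        selected_feature_ids=feat_ids,
        scaler=scaler,
        impute_values=medians,
        classifier=final,
        selection_eval=sel_eval,
        selection_predictions=oof,
        seed=seed,
    )


def _grid_candidates(grid: dict) -> list:
    keys = list(grid.keys())
    if not keys or any(len(grid[k]) == 0 for k in keys):
        raise SoldierError("empty parameter grid")
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def train_ft_soldier(
    train,
    av: AttackVector,
    family: str,
    seed: int,
    param_grid: dict | None = None,
    search: str = "exhaustive",
    n_random: int | None = None,
    n_bins: int = 5,
) -> Soldier:
    """Train one parameterized soldier: grid-search its parameters by selection rho."""
    if family not in FT_FAMILIES:
        raise SoldierError(f"unknown FT family {family!r}")
    if search not in ("exhaustive", "random"):
        raise SoldierError(f"unknown search mode {search!r}")
    grid = DEFAULT_FT_GRIDS[family] if param_grid is None else param_grid
    candidates = _grid_candidates(grid)
    if search == "random":
        m = len(candidates) if n_random is None else min(n_random, len(candidates))
        rng = np.random.default_rng(derive_seed(seed, "ft-random-search"))
        keep = np.sort(rng.choice(len(candidates), size=m, replace=False))
        candidates = [candidates[i] for i in keep]

    X, feat_ids, scaler, medians = _prepare_pipeline(train, av, n_bins)
    y = train.labels
    factory = FT_FAMILIES[family]

    best = None  # (eval, oof, params)
    for params in candidates:
        prototype = factory(dict(params), seed)
        oof = _oof_predictions(X, y, av.validation, prototype)
        ev = EvaluationResult.from_predictions(oof, y)
        if best is None or (ev.rho, ev.mcc) > (best[0].rho, best[0].mcc):
            best = (ev, oof, params)
    sel_eval, sel_oof, best_params = best
    final = factory(dict(best_params), seed)
    final.fit(X, y)
    return Soldier(
        phase="FT",
        classifier_family=family,
        attack_vector=av,
        best_params=dict(best_params),
        selected_feature_ids=feat_ids,
        scaler=scaler,
        impute_values=medians,
        classifier=final,
        selection_eval=sel_eval,
        selection_predictions=sel_oof,
        seed=seed,
    )


def evaluate_on_holdout(predictor, holdout) -> EvaluationResult:
    """Accuracy/MCC/rho of a fitted soldier or ensemble on holdout data."""
    pred = predictor.predict(holdout)
    return EvaluationResult.from_predictions(pred, holdout.labels)
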