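import numpy as np
import pytest

from conftest import make_dataset
from ito.metrics import EvaluationResult, confusion_counts, mcc
from ito.soldiers import (
    AttackVector,
    SoldierError,
    derive_seed,
    evaluate_on_holdout,
    generate_options_grid,
    sample_grid,
    train_ft_soldier,
    train_lig_soldier,
)
from ito.synthetic_data import SyntheticSpec, generate

AV = AttackVector(prep="standard", fss_method="mrmr", subset_size=5, validation="tenfold_cv")
TINY_RF_GRID = {"n_estimators": [10, 25], "criterion": ["gini"], "bootstrap": [True]}


def _separable(seed=0, n_train=60, n_valid=40, effect=10.0, n_features=80):
    spec = SyntheticSpec(n_train=n_train, n_valid=n_valid, n_features=n_features,
                         n_informative=5, n_redundant=3, effect_size=effect,
                         positive_fraction=0.4, missing_rate=0.02, seed=seed)
    return generate(spec)


# ---------------------------------------------------------------------------
# grid generation and sampling
# ---------------------------------------------------------------------------

def test_grid_is_full_cartesian_product():
    grid = generate_options_grid(
        ["none", "quantile", "robust", "standard"],
        [10, 50, 100, 150, 200, 250],
        ["jmi", "jmim", "mrmr"],
        ["tenfold_cv", "loocv"],
    )
    assert len(grid) == 4 * 6 * 3 * 2 == 144
    assert len(set(grid)) == 144  # no duplicate tuples


def test_singleton_sets_give_single_vector_and_empty_set_errors():
    grid = generate_options_grid(["standard"], [10], ["jmi"], ["loocv"])
    assert grid == [AttackVector("standard", "jmi", 10, "loocv")]
    with pytest.raises(SoldierError):
        generate_options_grid([], [10], ["jmi"], ["loocv"])


def test_grid_regeneration_is_identically_ordered():
    args = (["standard", "none"], [10, 50], ["jmi", "mrmr"], ["loocv"])
    assert generate_options_grid(*args) == generate_options_grid(*args)


def test_sample_grid_sizes_and_reproducibility():
    grid = generate_options_grid(["none", "quantile", "robust", "standard"],
                                 [10, 50, 100, 150, 200, 250],
                                 ["jmi", "jmim", "mrmr"], ["tenfold_cv", "loocv"])
    half = sample_grid(grid, 0.5, seed=7)
    assert len(half) == 72
    assert sample_grid(grid, 0.5, seed=7) == half
    assert sample_grid(grid, 0.5, seed=8) != half
    assert sorted(sample_grid(grid, 1.0, seed=3), key=str) == sorted(grid, key=str)


def test_repeated_half_samples_cover_the_grid():
    grid = generate_options_grid(["none", "quantile", "robust", "standard"],
                                 [10, 50, 100, 150, 200, 250],
                                 ["jmi", "jmim", "mrmr"], ["tenfold_cv", "loocv"])
    seen = set()
    for seed in range(20):
        seen.update(sample_grid(grid, 0.5, seed))
    assert len(seen) >= 0.99 * len(grid)


def test_derived_seeds_are_stable_and_distinct():
    assert derive_seed(42, "lig", 3) == derive_seed(42, "lig", 3)
    assert derive_seed(42, "lig", 3) != derive_seed(42, "lig", 4)
    assert 0 <= derive_seed(42, "x") < 2 ** 31


# ---------------------------------------------------------------------------
# LIG training
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family", ["decision_tree", "adaboost", "extra_trees"])
def test_lig_soldier_is_strong_on_separable_data(family):
    train, valid, _ = _separable(seed=1)
    s = train_lig_soldier(train, AV, family, seed=11)
    assert s.selection_eval.mcc > 0.9
    assert evaluate_on_holdout(s, valid).mcc > 0.9


def test_lig_soldier_beats_single_feature_threshold_oracle():
    """Out-of-fold MCC at least matches a best-threshold stump on the top feature."""
    train, _, _ = _separable(seed=2)
    s = train_lig_soldier(train, AV, "decision_tree", seed=3)
    # oracle: best single split on the soldier's own top-ranked feature
    col = train.subset_features(s.selected_feature_ids[:1]).matrix[:, 0]
    y = train.labels
    best = max(
        max(
            mcc(confusion_counts((col > t).astype(int), y)),
            mcc(confusion_counts((col <= t).astype(int), y)),
        )
        for t in np.unique(col)
    )
    assert s.selection_eval.mcc >= best - 0.1


def test_permuted_labels_give_near_zero_mcc():
    """Null distribution: shuffled labels should not be learnable."""
    base_train, _, _ = _separable(seed=4, effect=10.0, n_train=100)
    hits = 0
    for i in range(50):
        rng = np.random.default_rng(100 + i)
        shuffled = base_train.copy()
        shuffled.labels = rng.permutation(shuffled.labels)
        s = train_lig_soldier(shuffled, AV, "decision_tree", seed=i)
        hits += abs(s.selection_eval.mcc) < 0.3
    assert hits >= 45  # >= 95% of 50 runs within the null band


def test_lig_training_is_deterministic():
    train, _, _ = _separable(seed=5)
    a = train_lig_soldier(train, AV, "extra_trees", seed=9)
    b = train_lig_soldier(train, AV, "extra_trees", seed=9)
    assert a.selection_eval == b.selection_eval
    assert np.array_equal(a.selection_predictions, b.selection_predictions)


def test_subset_size_clamped_to_surviving_features():
    train, _, _ = _separable(seed=6, n_features=30)
    wide = AttackVector("standard", "mrmr", 500, "tenfold_cv")
    with pytest.warns(UserWarning, match="clamp"):
        s = train_lig_soldier(train, wide, "decision_tree", seed=1)
    assert len(s.selected_feature_ids) <= 30


def test_lig_soldier_has_no_params_and_unknown_family_errors():
    train, _, _ = _separable(seed=7, n_train=40, n_features=30)
    s = train_lig_soldier(train, AV, "decision_tree", seed=2)
    assert s.best_params == {} and s.phase == "LIG"
    with pytest.raises(SoldierError):
        train_lig_soldier(train, AV, "xgboost", seed=2)


def test_loocv_validation_protocol_runs():
    train, _, _ = _separable(seed=8, n_train=30, n_features=30)
    av = AttackVector("robust", "jmi", 5, "loocv")
    s = train_lig_soldier(train, av, "decision_tree", seed=4)
    assert s.selection_eval.n_evaluated == 30


# ---------------------------------------------------------------------------
# FT training
# ---------------------------------------------------------------------------

def test_single_point_grid_equals_plain_training():
    train, _, _ = _separable(seed=9)
    grid = {"n_estimators": [15], "criterion": ["gini"], "bootstrap": [True]}
    s = train_ft_soldier(train, AV, "random_forest", seed=6, param_grid=grid)
    assert s.best_params == {"n_estimators": 15, "criterion": "gini", "bootstrap": True}
    assert s.phase == "FT"


def test_random_search_over_full_grid_matches_exhaustive():
    train, _, _ = _separable(seed=10)
    ex = train_ft_soldier(train, AV, "random_forest", seed=6, param_grid=TINY_RF_GRID,
                          search="exhaustive")
    rnd = train_ft_soldier(train, AV, "random_forest", seed=6, param_grid=TINY_RF_GRID,
                           search="random", n_random=2)
    assert rnd.best_params == ex.best_params
    assert rnd.selection_eval == ex.selection_eval


def test_grid_winner_has_best_selection_rho():
    """The chosen assignment matches an independent evaluation of every candidate."""
    train, _, _ = _separable(seed=12, effect=1.0)  # imperfect regime so rho varies
    s = train_ft_soldier(train, AV, "random_forest", seed=8, param_grid=TINY_RF_GRID)
    rhos = {}
    for n_est in TINY_RF_GRID["n_estimators"]:
        grid1 = {"n_estimators": [n_est], "criterion": ["gini"], "bootstrap": [True]}
        cand = train_ft_soldier(train, AV, "random_forest", seed=8, param_grid=grid1)
        rhos[n_est] = cand.selection_eval.rho
    assert s.selection_eval.rho == max(rhos.values())


def test_empty_grid_is_hard_error():
    train, _, _ = _separable(seed=13, n_train=30, n_features=30)
    with pytest.raises(SoldierError):
        train_ft_soldier(train, AV, "random_forest", seed=1, param_grid={"n_estimators": []})


# ---------------------------------------------------------------------------
# holdout evaluation
# ---------------------------------------------------------------------------

class _ConstantPredictor:
    def __init__(self, value):
        self.value = value

    def predict(self, dataset):
        return np.full(dataset.n_samples, self.value, dtype=int)


def test_majority_class_predictor_on_balanced_holdout():
    holdout = make_dataset(np.zeros((10, 2)), [1] * 5 + [0] * 5)
    ev = evaluate_on_holdout(_ConstantPredictor(0), holdout)
    assert ev.accuracy == 0.5 and ev.mcc == 0.0


def test_perfect_predictor_scores_ones():
    train, valid, _ = _separable(seed=14)
    s = train_lig_soldier(train, AV, "extra_trees", seed=5)
    ev = evaluate_on_holdout(s, valid)
    assert (ev.accuracy, ev.mcc, ev.rho) == (1.0, 1.0, 1.0)


def test_holdout_eval_equals_hand_confusion_tally():
    train, valid, _ = _separable(seed=15, effect=1.0, n_valid=20)
    s = train_lig_soldier(train, AV, "decision_tree", seed=7)
    pred = s.predict(valid)
    ev = evaluate_on_holdout(s, valid)
    tp = sum(1 for p, a in zip(pred, valid.labels) if p == 1 and a == 1)
    tn = sum(1 for p, a in zip(pred, valid.labels) if p == 0 and a == 0)
    assert ev.confusion[:2] == (tp, tn)
    assert ev.accuracy == (tp + tn) / 20


def test_holdout_feature_misalignment_is_error():
    train, valid, _ = _separable(seed=16)
    s = train_lig_soldier(train, AV, "decision_tree", seed=7)
    stripped = valid.subset_features([f for f in valid.feature_ids
                                     if f not in s.selected_feature_ids])
    with pytest.raises(Exception):
        s.predict(stripped)


def test_pipeline_never_touches_holdout(rng):
    """Leakage check: the fitted soldier is identical whatever the holdout holds."""
    train, valid, _ = _separable(seed=17)
    s1 = train_lig_soldier(train, AV, "decision_tree", seed=3)
    valid.matrix *= 100
    s2 = train_lig_soldier(train, AV, "decision_tree", seed=3)
    assert s1.selection_eval == s2.selection_eval
    assert s1.selected_feature_ids == s2.selected_feature_ids
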