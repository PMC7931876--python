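import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from ehrnet import (
    SplitPlan,
    boxplot_select,
    deviance,
    evaluate_classifier,
    gini_impurity,
    l1_logistic_path,
    lasso_lambda_max,
    lasso_select,
    misclassification_error,
    rf_importances,
    run_selection,
    select_rf,
)


def _planted_design(n=500, p=8, beta=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        (rng.random((n, p)) < 0.3).astype(float), columns=[f"x{j}" for j in range(p)]
    )
    logit = -0.5 + beta * X["x0"].to_numpy()
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float), name="y")
    return X, y


# ---------------------------------------------------------------- loss terms


def test_gini_impurity_hand_values():
    assert gini_impurity([0.5, 0.5]) == pytest.approx(0.5)
    assert gini_impurity([0.9, 0.1]) == pytest.approx(0.18)
    assert gini_impurity([1.0, 0.0]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        gini_impurity([0.9, 0.3])


def test_deviance_hand_value_and_length_check():
    assert deviance([1.0, 0.0], [0.5, 0.5]) == pytest.approx(2.772589, abs=1e-6)
    assert deviance([1.0], [1.0]) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        deviance([1.0, 0.0], [0.5])


def test_misclassification_error_hand_value():
    assert misclassification_error([1, 0, 1, 0], [1, 0, 0, 0]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        misclassification_error([], [])


# ------------------------------------------------------------- boxplot rule


def test_boxplot_selects_only_the_outlier():
    values = pd.Series(
        [0.9, 1.0, 1.1, 1.0, 0.95, 5.0], index=[f"v{i}" for i in range(6)]
    )
    selected, threshold = boxplot_select(values)
    assert selected == frozenset({"v5"})
    assert threshold < 5.0
    # the notch-scaled variant also isolates this gross outlier
    selected_notch, _ = boxplot_select(values, sqrt_n_scaling=True)
    assert "v5" in selected_notch


def test_boxplot_is_scale_equivariant():
    rng = np.random.default_rng(3)
    v = rng.random(40)
    v[7] = 10.0
    mask1, _ = boxplot_select(v)
    mask2, _ = boxplot_select(v * 37.5)
    assert np.array_equal(mask1, mask2)


def test_boxplot_degenerate_and_small_inputs():
    mask, _ = boxplot_select(np.ones(10))
    assert not mask.any()
    with pytest.raises(ValueError, match="at least 5"):
        boxplot_select([1.0, 2.0])


# ----------------------------------------------------------- random forest


def test_rf_importances_rank_the_planted_predictor_first():
    X, y = _planted_design(seed=1)
    imp = rf_importances(X, y, n_trees=80, seed=1)
    assert list(imp.index) == list(X.columns)
    assert imp["mda"].idxmax() == "x0"
    assert imp["gini_decrease"].idxmax() == "x0"
    assert (imp["gini_decrease"] >= 0).all()
    selected, thresholds = select_rf(imp, mode="union")
    assert "x0" in selected
    assert set(thresholds) == {"mda", "gini_decrease"}


def test_rf_importances_are_seed_deterministic():
    X, y = _planted_design(seed=2)
    a = rf_importances(X, y, n_trees=30, seed=9)
    b = rf_importances(X, y, n_trees=30, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_rf_importances_vanish_on_permuted_outcome():
    X, y = _planted_design(seed=4)
    y_null = pd.Series(np.random.default_rng(5).permutation(y.to_numpy()))
    imp_null = rf_importances(X, y_null, n_trees=80, seed=4)
    imp_alt = rf_importances(X, y, n_trees=80, seed=4)
    assert imp_null["mda"].max() < imp_alt.loc["x0", "mda"] / 3
    with pytest.raises(ValueError, match="single class"):
        rf_importances(X, pd.Series(np.zeros(len(X))), n_trees=5)


def test_duplicated_predictor_splits_importance():
    X, y = _planted_design(n=800, seed=6)
    X = X.copy()
    X["x0_dup"] = X["x0"]
    imp = rf_importances(X, y, n_trees=120, seed=6)
    top2 = set(imp["gini_decrease"].nlargest(2).index)
    assert top2 == {"x0", "x0_dup"}
    # sharing splits roughly halves each copy's credit
    solo = rf_importances(X.drop(columns=["x0_dup"]), y, n_trees=120, seed=6)
    assert imp.loc["x0", "gini_decrease"] < 0.8 * solo.loc["x0", "gini_decrease"]


def test_select_rf_intersection_is_subset_of_union():
    X, y = _planted_design(seed=7)
    imp = rf_importances(X, y, n_trees=60, seed=7)
    uni, _ = select_rf(imp, mode="union")
    inter, _ = select_rf(imp, mode="intersection")
    assert inter <= uni
    with pytest.raises(ValueError, match="mode"):
        select_rf(imp, mode="xor")


# ------------------------------------------------------------------- lasso


def test_lambda_above_lambda_max_selects_nothing():
    X, y = _planted_design(n=400, seed=8)
    lmax = lasso_lambda_max(X, y)
    assert lmax > 0
    res = lasso_select(X, y, lambda_=lmax * 1.01)
    assert res.selected == frozenset()


def test_unpenalized_limit_matches_statsmodels():
    X, y = _planted_design(n=400, p=4, seed=9)
    res = lasso_select(X, y, lambda_=0.0)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    ours = res.model.coef_.ravel()
    theirs = sm_fit.params[list(X.columns)].to_numpy()
    assert np.max(np.abs(ours - theirs)) < 1e-4


def test_coordinate_descent_matches_saga_along_the_path():
    X, y = _planted_design(n=400, seed=12)
    Xa, ya = X.to_numpy(dtype=float), y.to_numpy(dtype=float)
    lmax = lasso_lambda_max(Xa, ya)
    lambdas = np.geomspace(lmax, lmax * 0.02, 8)
    b0s, betas = l1_logistic_path(Xa, ya, lambdas, tol=1e-12)
    for lam, b0, beta in zip(lambdas[1:], b0s[1:], betas[1:]):
        ref = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=50000, tol=1e-8
        ).fit(Xa, ya)
        assert np.max(np.abs(beta - ref.coef_.ravel())) < 1e-4
        assert abs(b0 - ref.intercept_[0]) < 1e-4


def test_path_solver_rejects_bad_penalty_grids():
    X, y = _planted_design(n=200, seed=13)
    with pytest.raises(ValueError, match="decreasing"):
        l1_logistic_path(X, y, [0.1, 1.0])
    with pytest.raises(ValueError, match="nonnegative"):
        l1_logistic_path(X, y, [-1.0])
    with pytest.raises(ValueError, match="single class"):
        l1_logistic_path(X, np.zeros(len(X)), [1.0])


def test_cv_lasso_recovers_the_planted_predictor():
    X, y = _planted_design(n=600, seed=10)
    res = lasso_select(X, y, cv_folds=5, seed=10)
    assert "x0" in res.selected
    assert res.threshold > 0
    # the one-standard-error penalty is never below the deviance minimizer
    res_min = lasso_select(X, y, cv_folds=5, seed=10, lambda_rule="min")
    assert res.threshold >= res_min.threshold
    with pytest.raises(ValueError, match="lambda_rule"):
        lasso_select(X, y, lambda_rule="2se")
    with pytest.raises(ValueError, match="single class"):
        lasso_select(X, pd.Series(np.zeros(len(X))))


# -------------------------------------------------------------- evaluation


class _FixedProba:
    def __init__(self, proba):
        self._p = np.asarray(proba, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self._p, self._p])


def test_evaluate_classifier_hand_example():
    y = [0.0, 0.0, 1.0, 1.0]
    metrics = evaluate_classifier(_FixedProba([0.1, 0.6, 0.4, 0.9]), np.zeros((4, 1)), y)
    assert metrics["roc_auc"] == pytest.approx(0.75)
    assert metrics["accuracy"] == pytest.approx(0.5)
    assert metrics["precision"] == pytest.approx(0.5)
    assert metrics["recall"] == pytest.approx(0.5)


def test_evaluate_classifier_perfect_and_degenerate():
    y = [0.0, 1.0]
    perfect = evaluate_classifier(_FixedProba([0.01, 0.99]), np.zeros((2, 1)), y)
    assert perfect == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "roc_auc": 1.0}
    with pytest.warns(UserWarning, match="single-class"):
        one_class = evaluate_classifier(_FixedProba([0.7, 0.7]), np.zeros((2, 1)), [1.0, 1.0])
    assert one_class["roc_auc"] is None
    with pytest.raises(ValueError, match="empty"):
        evaluate_classifier(_FixedProba([]), np.zeros((0, 1)), [])


def test_run_selection_both_arms_end_to_end():
    X, y = _planted_design(n=600, seed=11)
    plan = SplitPlan(train_fraction=0.7, cv_folds=5, seed=11)
    rf = run_selection(X, y, method="rf", plan=plan, n_trees=60, seed=11)
    lasso = run_selection(X, y, method="lasso", plan=plan, seed=11)
    assert rf.method == "RF" and lasso.method == "LASSO"
    for res in (rf, lasso):
        assert "x0" in res.selected
        assert 0.5 < res.metrics["accuracy"] <= 1.0
        assert res.metrics["roc_auc"] > 0.5
    with pytest.raises(ValueError, match="method"):
        run_selection(X, y, method="pca")


def test_split_plan_is_stratified_and_validated():
    X, y = _planted_design(n=200, seed=12)
    X_train, X_test, y_train, y_test = SplitPlan(seed=12).split(X, y)
    assert len(X_train) == 140 and len(X_test) == 60
    assert abs(y_train.mean() - y_test.mean()) < 0.03
    with pytest.raises(ValueError):
        SplitPlan(train_fraction=1.2)
    with pytest.raises(ValueError):
        SplitPlan(cv_folds=1)
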