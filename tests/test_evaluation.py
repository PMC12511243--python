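"""Model grid and evaluation protocol: fold assignment, the 17 variants,
metric identities, Bland-Altman, and grid mechanics."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_table
from ppgbp.evaluation import (
    MODEL_VARIANTS,
    EvalResult,
    ModelSpec,
    bland_altman,
    best_models,
    compute_metrics,
    evaluate_cell,
    fit_predict,
    grid_frame,
    model_specs,
    run_grid,
    stratified_kfold,
)
from ppgbp.features import feature_names
from oracles import gp_posterior_mean


# -- stratified folds -------------------------------------------------------

def test_folds_partition_and_balance(table56):
    folds = stratified_kfold(table56, K=10, seed=1)
    assert len(folds) == len(table56)
    assert set(folds) == set(range(10))
    for cat, sub in table56.groupby("category", observed=True):
        sizes = np.bincount(folds[sub.index.to_numpy()], minlength=10)
        assert sizes.max() - sizes.min() <= 1


def test_folds_deterministic(table56):
    a = stratified_kfold(table56, K=10, seed=42)
    b = stratified_kfold(table56, K=10, seed=42)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, stratified_kfold(table56, K=10, seed=43))


def test_small_stratum_error_names_it(table56):
    with pytest.raises(ValueError, match="elevated"):
        stratified_kfold(table56, K=12, seed=0)


def test_group_by_subject_keeps_subjects_whole(table224):
    folds = stratified_kfold(table224, K=10, seed=5, group_by_subject=True)
    df = pd.DataFrame({"subject": table224["subject_id"], "fold": folds})
    assert (df.groupby("subject")["fold"].nunique() == 1).all()


# -- model variants ---------------------------------------------------------

def test_seventeen_variants():
    assert len(MODEL_VARIANTS) == 17
    assert len({s.variant for s in MODEL_VARIANTS}) == 17
    fams = {s.family for s in MODEL_VARIANTS}
    assert fams == {"linear", "tree", "svr", "gpr"}


def test_simple_linear_recovers_noiseless_line():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 3))
    y = 2.0 * X[:, 0] + 1.0
    Xt = rng.normal(size=(20, 3))
    pred = fit_predict(model_specs(["simple_linear"])[0], X[:40], y[:40], X[40:])
    assert np.max(np.abs(pred - y[40:])) < 1e-8


def test_matern_gpr_interpolates_smooth_function():
    """Noiseless smooth 1-D target: after hyperparameter optimization the
    GP nearly interpolates its training points, and the prediction agrees
    with a direct kernel-matrix solve using the fitted kernel."""
    from sklearn.gaussian_process import GaussianProcessRegressor

    from ppgbp.evaluation import _gpr_kernel

    rng = np.random.default_rng(1)
    X = np.sort(rng.uniform(-3, 3, size=(40, 1)), axis=0)
    y = np.sin(X[:, 0]) + 0.3 * X[:, 0]
    pred = fit_predict(model_specs(["matern52_gpr"])[0], X, y, X)
    assert np.max(np.abs(pred - y)) < 1e-3

    # oracle: the same standardization and kernel, solved by hand
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    gp = GaussianProcessRegressor(
        kernel=_gpr_kernel("matern52"), normalize_y=True,
        n_restarts_optimizer=0, random_state=0,
    ).fit(Xz, y)
    manual = gp_posterior_mean(gp.kernel_, Xz, y, Xz, alpha=gp.alpha)
    assert pred == pytest.approx(manual, abs=1e-6)


def test_finer_trees_fit_train_no_worse():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(8, 2))
    y = rng.normal(size=8)
    fine = fit_predict(model_specs(["fine_tree"])[0], X, y, X)
    med = fit_predict(model_specs(["medium_tree"])[0], X, y, X)
    assert np.mean(np.abs(fine - y)) <= np.mean(np.abs(med - y)) + 1e-12


@pytest.mark.parametrize("spec", MODEL_VARIANTS, ids=lambda s: s.variant)
def test_all_variants_predict_finite(spec):
    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 5))
    y = 120 + 5 * X[:, 0] + rng.normal(size=50)
    pred = fit_predict(spec, X[:40], y[:40], X[40:])
    assert pred.shape == (10,)
    assert np.isfinite(pred).all()


def test_no_test_information_in_scaling():
    """Shifting the test rows must not change training: predictions react
    only through the (frozen) training-fold standardization."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 3))
    y = X @ [1.0, -2.0, 0.5] + 100
    spec = model_specs(["simple_linear"])[0]
    p1 = fit_predict(spec, X[:50], y[:50], X[50:])
    p2 = fit_predict(spec, X[:50], y[:50], X[50:] + 10.0)
    assert not np.allclose(p1, p2)  # predictions move with the inputs...
    p3 = fit_predict(spec, X[:50], y[:50], X[50:])
    assert np.array_equal(p1, p3)  # ...but training is unaffected


# -- metrics ----------------------------------------------------------------

def test_perfect_prediction_metrics():
    m = compute_metrics([120.0, 130.0, 140.0], [120.0, 130.0, 140.0])
    assert m.mae == m.mse == m.rmse == 0.0
    assert m.r2 == 1.0


def test_mean_prediction_gives_zero_r2():
    ref = np.array([110.0, 120.0, 130.0, 140.0])
    m = compute_metrics(np.full(4, ref.mean()), ref)
    assert m.r2 == pytest.approx(0.0, abs=1e-12)


def test_metrics_hand_example():
    m = compute_metrics([120.0, 130.0], [118.0, 134.0])
    assert m.mae == pytest.approx(3.0)
    assert m.mse == pytest.approx(10.0)
    assert m.rmse == pytest.approx(np.sqrt(10.0))


def test_constant_reference_r2_undefined():
    with pytest.warns(UserWarning, match="constant"):
        m = compute_metrics([1.0, 2.0], [5.0, 5.0])
    assert m.r2 is None


def test_rmse_mse_identity_random():
    rng = np.random.default_rng(5)
    m = compute_metrics(rng.normal(size=100), rng.normal(size=100))
    assert m.rmse**2 == pytest.approx(m.mse, abs=1e-12)


# -- Bland-Altman -----------------------------------------------------------

def test_agreement_zero_differences():
    a = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert a.bias == 0 and a.loa_low == 0 == a.loa_high
    assert a.ci_low == 0 == a.ci_high


def test_agreement_symmetric_differences():
    ref = np.zeros(4)
    a = bland_altman(np.array([1.0, -1.0, 1.0, -1.0]), ref)
    assert a.bias == 0
    assert a.ci_low == pytest.approx(-a.ci_high)
    assert a.ci_low < 0 < a.ci_high


def test_agreement_hand_t_interval():
    # d = [2, 4, 6]: bias 4, sd 2, t_{0.975,2} = 4.303
    a = bland_altman(np.array([2.0, 4.0, 6.0]), np.zeros(3))
    assert a.bias == pytest.approx(4.0)
    half = 4.302652729911275 * 2.0 / np.sqrt(3)
    assert a.ci_low == pytest.approx(4.0 - half, abs=1e-6)
    assert a.ci_high == pytest.approx(4.0 + half, abs=1e-6)
    assert a.loa_low == pytest.approx(4.0 - 1.96 * 2.0)
    assert a.loa_high == pytest.approx(4.0 + 1.96 * 2.0)
    assert a.ci_low <= a.bias <= a.ci_high


# -- grid mechanics ---------------------------------------------------------

def test_evaluate_cell_pooled_n_is_fold_sum(table56):
    res = evaluate_cell(
        table56, feature_names()[:5], model_specs(["medium_tree"])[0], "SBP",
        seed=2,
    )
    assert res.pooled.n == sum(m.n for m in res.fold_metrics) == len(table56)
    assert res.pooled.rmse**2 == pytest.approx(res.pooled.mse, abs=1e-12)


def test_run_grid_cell_count_and_best(table56):
    specs = model_specs(["simple_linear", "medium_tree", "linear_svr"])
    results = run_grid(table56, specs=specs, seed=3)
    assert len(results) == 3 * 3 * 2
    df = grid_frame(results)
    assert df["error"].isna().all()
    best = best_models(results)
    for row in best.itertuples(index=False):
        sub = df[(df.selector == row.selector) & (df.target == row.target)]
        assert row.mae == sub["mae"].min()


def test_failed_cell_is_flagged_not_fatal(table56):
    bogus = ModelSpec("nonsense", "bogus_model")
    results = run_grid(
        table56, specs=model_specs(["simple_linear"]) + [bogus],
        selectors=("f_test",), targets=("SBP",), seed=4,
    )
    assert len(results) == 2
    flagged = [r for r in results if r.error is not None]
    assert len(flagged) == 1 and flagged[0].spec.variant == "bogus_model"
    assert results[0].error is None


def test_grid_reproducible_with_fixed_seed(table56):
    specs = model_specs(["simple_linear", "squared_exponential_gpr"])
    r1 = run_grid(table56, specs=specs, selectors=("relieff",),
                  targets=("SBP",), seed=5)
    r2 = run_grid(table56, specs=specs, selectors=("relieff",),
                  targets=("SBP",), seed=5)
    for a, b in zip(r1, r2):
        assert a.pooled == b.pooled
        assert a.agreement == b.agreement
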