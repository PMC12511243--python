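"""Regression-model grid, stratified cross-validation, error metrics and
Bland-Altman agreement.

Seventeen regression variants from four families are evaluated per
(selector, target) cell with stratified K-fold cross-validation (K = 10,
strata = AHA category).  Predictor columns are z-scored on each training
fold only, and data-dependent steps (scaling, stepwise term selection,
hyperparameter optimization) are re-fit inside every fold, so no test
information leaks into training.

Families and variants
---------------------
* linear: ordinary least squares on main effects; with pairwise
  interactions; robust (IRLS, Tukey bisquare, c = 4.685); stepwise
  (forward-backward over mains + pairwise interactions, AICc criterion).
* tree: CART regression trees, min leaf size 4 / 12 / 36 (fine / medium
  / coarse).
* svr: epsilon-SVR with linear, quadratic, cubic and Gaussian kernels
  (kernel scale sqrt(p)/4, sqrt(p), 4 sqrt(p) for fine/medium/coarse);
  box constraint iqr(y)/1.349 and epsilon iqr(y)/13.49.
* gpr: Gaussian-process regression with constant mean and squared-
  exponential, Matern 5/2, exponential or rational-quadratic kernel plus
  a white-noise term; hyperparameters by marginal-likelihood
  maximization.

Metrics are the standard regression errors: MAE, MSE, RMSE = sqrt(MSE),
and r^2 = 1 - MSE(model)/MSE(baseline) where the baseline predicts the
mean of the reference values.  Agreement between predicted and reference
BP is summarized Bland-Altman style: bias, 1.96-SD limits of agreement,
and the t-based 95% confidence interval of the bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process import kernels as gpk
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .selection import SELECTORS, SelectionResult, TARGET_COLUMNS, rank_features

__all__ = [
    "ModelSpec",
    "Metrics",
    "AgreementReport",
    "EvalResult",
    "MODEL_VARIANTS",
    "model_specs",
    "stratified_kfold",
    "fit_predict",
    "compute_metrics",
    "bland_altman",
    "evaluate_cell",
    "run_grid",
    "grid_frame",
    "best_models",
]


@dataclass(frozen=True)
class ModelSpec:
    """One regression variant: family, variant name, hyperparameters."""

    family: str  # linear | tree | svr | gpr
    variant: str
    hyperparams: dict = field(default_factory=dict)


#: The 17 variants of the grid, in reporting order.
MODEL_VARIANTS: tuple[ModelSpec, ...] = (
    ModelSpec("linear", "simple_linear"),
    ModelSpec("linear", "interactions_linear"),
    ModelSpec("linear", "robust_linear", {"tuning_const": 4.685}),
    ModelSpec("linear", "stepwise_linear", {"max_terms": 15}),
    ModelSpec("tree", "fine_tree", {"min_samples_leaf": 4}),
    ModelSpec("tree", "medium_tree", {"min_samples_leaf": 12}),
    ModelSpec("tree", "coarse_tree", {"min_samples_leaf": 36}),
    ModelSpec("svr", "linear_svr", {"kernel": "linear"}),
    ModelSpec("svr", "quadratic_svr", {"kernel": "poly", "degree": 2}),
    ModelSpec("svr", "cubic_svr", {"kernel": "poly", "degree": 3}),
    ModelSpec("svr", "fine_gaussian_svr", {"kernel": "rbf", "scale_factor": 0.25}),
    ModelSpec("svr", "medium_gaussian_svr", {"kernel": "rbf", "scale_factor": 1.0}),
    ModelSpec("svr", "coarse_gaussian_svr", {"kernel": "rbf", "scale_factor": 4.0}),
    ModelSpec("gpr", "squared_exponential_gpr", {"kernel": "rbf"}),
    ModelSpec("gpr", "matern52_gpr", {"kernel": "matern52"}),
    ModelSpec("gpr", "exponential_gpr", {"kernel": "exponential"}),
    ModelSpec("gpr", "rational_quadratic_gpr", {"kernel": "rational_quadratic"}),
)


def model_specs(variants: list[str] | None = None) -> list[ModelSpec]:
    """All 17 specs, or a named subset (order preserved)."""
    if variants is None:
        return list(MODEL_VARIANTS)
    by_name = {s.variant: s for s in MODEL_VARIANTS}
    unknown = set(variants) - set(by_name)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    return [by_name[v] for v in variants]


@dataclass(frozen=True)
class Metrics:
    """MAE/MSE/RMSE/r^2 of one prediction set (errors in mmHg)."""

    mae: float
    mse: float
    rmse: float
    r2: float | None
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of predicted-minus-reference differences."""

    bias: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class EvalResult:
    """One grid cell: (selector, model, target) with per-fold and pooled
    metrics plus the agreement report.  ``error`` is set (and the rest
    None) when the cell failed."""

    selector: str
    spec: ModelSpec
    target: str
    fold_metrics: tuple[Metrics, ...] | None
    pooled: Metrics | None
    agreement: AgreementReport | None
    error: str | None = None


# ---------------------------------------------------------------------------
# cross-validation


def stratified_kfold(
    table: pd.DataFrame,
    K: int = 10,
    strata: str = "category",
    seed: int = 0,
    group_by_subject: bool = False,
) -> np.ndarray:
    """Deterministic stratified fold assignment (one label per row).

    Rows of each stratum are shuffled with a seeded RNG and dealt to the
    K folds round-robin, so within each stratum fold sizes differ by at
    most one.  With ``group_by_subject`` the unit of assignment is the
    subject (all of a subject's segments share a fold), guarding against
    sibling-segment leakage.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(len(table), -1, dtype=int)
    if group_by_subject:
        units = table.groupby("subject_id", observed=True)[strata].first()
        per_stratum: dict[str, list[str]] = {}
        for subj, cat in units.items():
            per_stratum.setdefault(cat, []).append(subj)
        subj_fold: dict[str, int] = {}
        for cat in sorted(per_stratum):
            members = sorted(per_stratum[cat])
            if len(members) < K:
                raise ValueError(
                    f"stratum {cat!r} has {len(members)} subjects, fewer than K={K}"
                )
            rng.shuffle(members)
            for i, s in enumerate(members):
                subj_fold[s] = i % K
        folds = table["subject_id"].map(subj_fold).to_numpy()
    else:
        for cat in sorted(table[strata].unique()):
            idx = np.flatnonzero((table[strata] == cat).to_numpy())
            if len(idx) < K:
                raise ValueError(
                    f"stratum {cat!r} has {len(idx)} rows, fewer than K={K}"
                )
            rng.shuffle(idx)
            for i, row in enumerate(idx):
                folds[row] = i % K
    assert (folds >= 0).all()
    return folds


# ---------------------------------------------------------------------------
# model fitting


def _interaction_design(X: np.ndarray) -> np.ndarray:
    """Columns of X plus all pairwise products x_i * x_j (i < j)."""
    n, p = X.shape
    cols = [X]
    for i in range(p):
        for j in range(i + 1, p):
            cols.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(cols)


def _solve_linear(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit; a rank-deficient design gets a tiny ridge jitter."""
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("singular linear design; applying ridge jitter 1e-8",
                      stacklevel=2)
        return np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ y)
    return np.linalg.lstsq(A, y, rcond=None)[0]


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + error variance
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _stepwise_fit(
    X: np.ndarray, y: np.ndarray, max_terms: int = 15, max_iter: int = 60
) -> list[int]:
    """Forward-backward term selection over a candidate design by AICc.

    Returns the indices of the selected columns of ``X`` (an intercept is
    always included implicitly).
    """
    n = len(y)
    selected: list[int] = []

    def score(terms: list[int]) -> float:
        A = np.hstack([np.ones((n, 1)), X[:, terms]]) if terms else np.ones((n, 1))
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        rss = float(np.sum((y - A @ beta) ** 2))
        return _aicc(rss, n, len(terms) + 1)

    current = score(selected)
    for _ in range(max_iter):
        changed = False
        if len(selected) < max_terms:
            cands = [c for c in range(X.shape[1]) if c not in selected]
            trials = [(score(selected + [c]), c) for c in cands]
            if trials:
                best, c = min(trials)
                if best < current - 1e-10:
                    selected.append(c)
                    current = best
                    changed = True
        if len(selected) > 1:
            trials = [
                (score([t for t in selected if t != c]), c) for c in selected
            ]
            best, c = min(trials)
            if best < current - 1e-10:
                selected.remove(c)
                current = best
                changed = True
        if not changed:
            break
    return selected


def _gpr_kernel(name: str) -> gpk.Kernel:
    base = {
        "rbf": gpk.RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3)),
        "matern52": gpk.Matern(length_scale=1.0, length_scale_bounds=(1e-2, 1e3),
                               nu=2.5),
        "exponential": gpk.Matern(length_scale=1.0, length_scale_bounds=(1e-2, 1e3),
                                  nu=0.5),
        "rational_quadratic": gpk.RationalQuadratic(
            length_scale=1.0, alpha=1.0, length_scale_bounds=(1e-2, 1e3)
        ),
    }[name]
    return (
        gpk.ConstantKernel(1.0, (1e-3, 1e3)) * base
        + gpk.WhiteKernel(1e-2, (1e-12, 1e1))
    )


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Fit one variant on the training rows and predict the test rows.

    Features are z-scored using training-fold statistics only; y-derived
    hyperparameters (SVR box constraint and epsilon) likewise use the
    training fold.  Predictions are finite for every test row.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd
    n, p = Xtr.shape

    if spec.family == "linear":
        if spec.variant == "simple_linear":
            A = np.hstack([np.ones((n, 1)), Xtr])
            beta = _solve_linear(A, y_train)
            return np.hstack([np.ones((len(Xte), 1)), Xte]) @ beta
        if spec.variant == "interactions_linear":
            A = np.hstack([np.ones((n, 1)), _interaction_design(Xtr)])
            beta = _solve_linear(A, y_train)
            return np.hstack(
                [np.ones((len(Xte), 1)), _interaction_design(Xte)]
            ) @ beta
        if spec.variant == "robust_linear":
            c = spec.hyperparams.get("tuning_const", 4.685)
            A = sm.add_constant(Xtr, has_constant="add")
            At = sm.add_constant(Xte, has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.RLM(y_train, A, M=sm.robust.norms.TukeyBiweight(c=c)).fit()
            return np.asarray(At @ res.params)
        if spec.variant == "stepwise_linear":
            D = _interaction_design(Xtr)
            Dt = _interaction_design(Xte)
            terms = _stepwise_fit(D, y_train,
                                  max_terms=spec.hyperparams.get("max_terms", 15))
            A = np.hstack([np.ones((n, 1)), D[:, terms]])
            beta = _solve_linear(A, y_train)
            return np.hstack([np.ones((len(Dt), 1)), Dt[:, terms]]) @ beta
    elif spec.family == "tree":
        model = DecisionTreeRegressor(
            min_samples_leaf=spec.hyperparams["min_samples_leaf"], random_state=0
        )
        return model.fit(Xtr, y_train).predict(Xte)
    elif spec.family == "svr":
        iqr_y = float(np.subtract(*np.percentile(y_train, [75, 25])))
        if iqr_y == 0:
            iqr_y = 1.349  # degenerate target spread; fall back to unit C
        C = iqr_y / 1.349
        eps = iqr_y / 13.49
        kw: dict = {"C": C, "epsilon": eps, "kernel": spec.hyperparams["kernel"]}
        if kw["kernel"] == "poly":
            kw.update(degree=spec.hyperparams["degree"], gamma="scale", coef0=1.0)
        elif kw["kernel"] == "rbf":
            scale = spec.hyperparams["scale_factor"] * np.sqrt(p)
            kw["gamma"] = 1.0 / scale**2
        return SVR(**kw).fit(Xtr, y_train).predict(Xte)
    elif spec.family == "gpr":
        model = GaussianProcessRegressor(
            kernel=_gpr_kernel(spec.hyperparams["kernel"]),
            normalize_y=True,  # constant (training-mean) prior mean
            n_restarts_optimizer=0,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, y_train)
        return model.predict(Xte)
    raise ValueError(f"unknown model spec {spec}")


# ---------------------------------------------------------------------------
# metrics and agreement


def compute_metrics(pred: np.ndarray, ref: np.ndarray) -> Metrics:
    """MAE, MSE, RMSE and r^2 of predictions against reference values.

    ``r^2 = 1 - MSE(model) / MSE(baseline)`` with the baseline predicting
    ``mean(ref)``; for a constant reference r^2 is undefined and reported
    as None with a warning.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(pred) != len(ref) or len(ref) < 2:
        raise ValueError("pred and ref must have equal length >= 2")
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    baseline = float(np.mean((ref - ref.mean()) ** 2))
    if baseline == 0:
        warnings.warn("constant reference; r^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - mse / baseline)
    return Metrics(mae=mae, mse=mse, rmse=rmse, r2=r2, n=len(ref))


def bland_altman(
    pred: np.ndarray, ref: np.ndarray, confidence: float = 0.95
) -> AgreementReport:
    """Bland-Altman summary of d = pred - ref.

    Limits of agreement are ``bias +/- 1.96 sd(d)`` (sample sd, ddof=1);
    the confidence interval of the bias is the exact t interval
    ``bias +/- t_{1-(1-conf)/2, n-1} sd(d)/sqrt(n)``.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    d = pred - ref
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tq = float(sstats.t.ppf(1 - (1 - confidence) / 2, n - 1))
    half = tq * sd / np.sqrt(n)
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        ci_low=bias - half,
        ci_high=bias + half,
        n=n,
    )


# ---------------------------------------------------------------------------
# the grid


def evaluate_cell(
    table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    spec: ModelSpec,
    target: str,
    selector: str = "",
    K: int = 10,
    seed: int = 0,
    group_by_subject: bool = False,
    folds: np.ndarray | None = None,
) -> EvalResult:
    """Cross-validated evaluation of one (feature subset, model, target)."""
    ycol = TARGET_COLUMNS[target]
    X = table[list(features)].to_numpy(dtype=float)
    y = table[ycol].to_numpy(dtype=float)
    if folds is None:
        folds = stratified_kfold(table, K=K, seed=seed,
                                 group_by_subject=group_by_subject)
    fold_metrics = []
    pred_all = np.empty(len(y))
    for f in range(int(folds.max()) + 1):
        test = folds == f
        train = ~test
        pred = fit_predict(spec, X[train], y[train], X[test])
        if not np.isfinite(pred).all():
            raise ValueError(f"non-finite predictions in fold {f}")
        pred_all[test] = pred
        fold_metrics.append(compute_metrics(pred, y[test]))
    pooled = compute_metrics(pred_all, y)
    assert pooled.n == sum(m.n for m in fold_metrics)
    return EvalResult(
        selector=selector,
        spec=spec,
        target=target,
        fold_metrics=tuple(fold_metrics),
        pooled=pooled,
        agreement=bland_altman(pred_all, y),
    )


def run_grid(
    table: pd.DataFrame,
    selectors: tuple[str, ...] = ("f_test", "mrmr", "relieff"),
    specs: list[ModelSpec] | None = None,
    targets: tuple[str, ...] = ("SBP", "DBP"),
    K: int = 10,
    k: int = 15,
    seed: int = 0,
    group_by_subject: bool = False,
) -> list[EvalResult]:
    """The full experiment grid: selectors x model variants x targets.

    Feature selection is computed once per (selector, target); each cell
    is then evaluated by stratified K-fold CV with a shared fold
    assignment.  Per-cell failures are returned as flagged rows (``error``
    set) rather than aborting the grid.
    """
    if specs is None:
        specs = list(MODEL_VARIANTS)
    folds = stratified_kfold(table, K=K, seed=seed,
                             group_by_subject=group_by_subject)
    results: list[EvalResult] = []
    for sel in selectors:
        if sel not in SELECTORS:
            raise ValueError(f"unknown selector {sel!r}")
        for target in targets:
            selection = rank_features(table, sel, target, k=k)
            for spec in specs:
                try:
                    results.append(
                        evaluate_cell(
                            table, selection.top_k, spec, target,
                            selector=sel, K=K, seed=seed, folds=folds,
                        )
                    )
                except Exception as exc:  # flagged row, grid continues
                    results.append(
                        EvalResult(
                            selector=sel, spec=spec, target=target,
                            fold_metrics=None, pooled=None, agreement=None,
                            error=f"{type(exc).__name__}: {exc}",
                        )
                    )
    return results


def grid_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Tabular view of grid results (one row per cell)."""
    rows = []
    for r in results:
        row = {
            "selector": r.selector,
            "model": r.spec.variant,
            "family": r.spec.family,
            "target": r.target,
            "error": r.error,
        }
        if r.pooled is not None:
            row.update(
                rmse=r.pooled.rmse, r2=r.pooled.r2, mse=r.pooled.mse,
                mae=r.pooled.mae, n=r.pooled.n,
                bias=r.agreement.bias, ci_low=r.agreement.ci_low,
                ci_high=r.agreement.ci_high,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def best_models(results: list[EvalResult]) -> pd.DataFrame:
    """Best (minimum pooled MAE) model per (selector, target)."""
    df = grid_frame(results)
    ok = df[df["error"].isna()]
    idx = ok.groupby(["selector", "target"], observed=True)["mae"].idxmin()
    return ok.loc[idx].reset_index(drop=True)
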