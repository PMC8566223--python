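"""Consensus association analysis between search variables and performance.

Seven statistical methods each flag (predictor, response, direction)
candidates on a standardised team x predictor design matrix; an association
is reported only when at least ``min_methods`` (default 3) methods agree,
with a consistent direction.  The consensus filter — not any single method —
is the contract: individually the methods are deliberately heterogeneous
(parametric inference, sparse selection, stability selection, tree
ensembles) so that agreement is informative.

Methods
-------
ols
    Multiple linear regression; per-coefficient two-sided p < 0.05.
ridge
    Ridge regression at a cross-validated penalty with a max-statistic
    permutation test (family-wise): a coefficient is flagged when its
    magnitude exceeds the permutation distribution of the largest
    coefficient magnitude at the 0.05 level.
lasso
    Lasso at a cross-validated penalty (one-standard-error rule); nonzero
    coefficients are flagged.
lars
    Least-angle regression with post-selection inference approximated by
    multi-split sample splitting: on each of ``n_splits`` random half-splits
    the LARS active set is selected on one half and its coefficients tested
    by ordinary least squares on the held-out half; the per-predictor median
    p-value across splits (1 where unselected) must fall below 0.05.  Sample
    splitting makes the post-selection tests valid by construction.
stepwise
    Forward stepwise regression (BIC-guided selection) with the same
    multi-split selective-inference scheme.
rf / gbt
    Random-forest and gradient-boosted-tree importances with a permutation
    strategy on an augmented set of noise variables: the design is augmented
    with a permuted (shadow) copy of every predictor, and a real predictor
    is flagged only when its importance exceeds both the largest shadow
    importance and a family-wise response-permutation cutoff (95th
    percentile of the maximum importance over refits on permuted responses).
    Tree importances are unsigned, so the direction is taken from the
    Spearman correlation between the predictor and the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lars, Lasso, LassoCV, Ridge, RidgeCV

__all__ = ["AssociationResult", "ALL_METHODS", "associate"]

ALL_METHODS = ("ols", "ridge", "lasso", "lars", "stepwise", "rf", "gbt")


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    response: str
    direction: str  # positive | negative
    supporting_methods: int
    method_flags: Mapping[str, str] = field(default_factory=dict)  # method -> direction
    reported: bool = False
    conflict: bool = False


def _standardize(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Zero-mean unit-variance columns; constant predictors are dropped."""
    kept, columns = [], []
    for name in frame.columns:
        values = frame[name].astype(float).to_numpy()
        sd = values.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"predictor {name!r} is constant and was dropped", stacklevel=3)
            continue
        kept.append((values - values.mean()) / sd)
        columns.append(name)
    if not kept:
        raise ValueError("no usable (non-constant) predictors")
    return np.column_stack(kept), columns


def _sign(value: float) -> str:
    return "positive" if value > 0 else "negative"


# --- individual methods: each returns {predictor_name: direction} ----------


def _method_ols(X, y, names, rng, cfg) -> dict[str, str]:
    n, p = X.shape
    if n <= p + 1:
        warnings.warn("ols skipped: fewer observations than parameters", stacklevel=3)
        return {}
    model = sm.OLS(y, sm.add_constant(X)).fit()
    flags = {}
    for j, name in enumerate(names):
        if model.pvalues[j + 1] < cfg["alpha"]:
            flags[name] = _sign(model.params[j + 1])
    return flags


def _method_ridge(X, y, names, rng, cfg) -> dict[str, str]:
    alphas = np.logspace(-2, 3, 30)
    fit = RidgeCV(alphas=alphas).fit(X, y)
    model = Ridge(alpha=fit.alpha_).fit(X, y)
    observed = np.abs(model.coef_)
    null_max = np.empty(cfg["n_permutations"])
    for i in range(cfg["n_permutations"]):
        perm = Ridge(alpha=fit.alpha_).fit(X, rng.permutation(y))
        null_max[i] = np.max(np.abs(perm.coef_))
    flags = {}
    for j, name in enumerate(names):
        p_value = (1 + np.sum(null_max >= observed[j])) / (cfg["n_permutations"] + 1)
        if p_value < cfg["alpha"]:
            flags[name] = _sign(model.coef_[j])
    return flags


def _method_lasso(X, y, names, rng, cfg) -> dict[str, str]:
    """Lasso at a cross-validated penalty, using the one-standard-error rule
    (largest penalty whose CV error is within one SE of the minimum)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = LassoCV(cv=5, random_state=int(rng.integers(0, 2**31 - 1))).fit(X, y)
        mean_mse = cv.mse_path_.mean(axis=1)
        se_mse = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
        best = int(np.argmin(mean_mse))
        within = np.flatnonzero(mean_mse <= mean_mse[best] + se_mse[best])
        alpha_1se = float(cv.alphas_[within.min()])  # alphas_ descend
        model = Lasso(alpha=alpha_1se).fit(X, y)
    return {name: _sign(c) for name, c in zip(names, model.coef_) if c != 0}


def _lars_select(X, y, max_terms) -> list[int]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Lars(n_nonzero_coefs=max_terms).fit(X, y)
    return [int(j) for j in np.flatnonzero(model.coef_)]


def _stepwise_select(X, y) -> list[int]:
    """Greedy forward selection minimising BIC; returns selected indices."""
    n, p = X.shape
    selected: list[int] = []
    best_bic = sm.OLS(y, np.ones((n, 1))).fit().bic
    while len(selected) < min(p, n - 2):
        candidates = [j for j in range(p) if j not in selected]
        scores = []
        for j in candidates:
            design = sm.add_constant(X[:, selected + [j]])
            scores.append((sm.OLS(y, design).fit().bic, j))
        bic, j = min(scores)
        if bic >= best_bic:
            break
        best_bic = bic
        selected.append(j)
    return selected


def _multi_split_flags(X, y, names, rng, cfg, select) -> dict[str, str]:
    """Selective inference by multi-split sample splitting.

    Each split selects predictors on one random half and tests the selected
    model by OLS on the held-out half, Bonferroni-corrected for the size of
    the selected model.  Per predictor, the median corrected p-value across
    splits (1 where unselected) must fall below ``alpha``; the direction is
    the aggregated sign of the held-out coefficients.
    """
    n, p = X.shape
    p_values = np.ones((cfg["n_splits"], p))
    sign_sum = np.zeros(p)
    for s in range(cfg["n_splits"]):
        order = rng.permutation(n)
        train, test = order[: n // 2], order[n // 2 :]
        if np.ptp(y[train]) == 0 or np.ptp(y[test]) == 0:
            continue
        selected = select(X[train], y[train])
        if not selected or len(selected) + 2 > len(test):
            continue
        fit = sm.OLS(y[test], sm.add_constant(X[np.ix_(test, selected)])).fit()
        for k, j in enumerate(selected):
            # Bonferroni over the selected model: the standard multi-split
            # correction for having searched all predictors
            p_values[s, j] = min(1.0, fit.pvalues[k + 1] * len(selected))
            if p_values[s, j] < cfg["alpha"]:
                sign_sum[j] += np.sign(fit.params[k + 1])
    flags = {}
    for j, name in enumerate(names):
        if np.median(p_values[:, j]) < cfg["alpha"] and sign_sum[j] != 0:
            flags[name] = _sign(sign_sum[j])
    return flags


def _method_lars(X, y, names, rng, cfg) -> dict[str, str]:
    max_terms = min(cfg["max_lars_terms"], X.shape[1])
    return _multi_split_flags(X, y, names, rng, cfg,
                              lambda Xt, yt: _lars_select(Xt, yt, max_terms))


def _method_stepwise(X, y, names, rng, cfg) -> dict[str, str]:
    return _multi_split_flags(X, y, names, rng, cfg, _stepwise_select)


def _shadow_importance_flags(model_cls, X, y, names, rng, cfg) -> dict[str, str]:
    """Tree importance with a noise-augmented, permutation-calibrated cutoff.

    The design is augmented with a permuted (shadow) copy of every predictor
    and a real predictor must beat the largest shadow importance.  Because a
    chance in-sample correlation beats uncorrelated shadows, the cutoff is
    additionally calibrated family-wise against a response-permutation null:
    the 95th percentile of the maximum real-feature importance over refits
    on permuted responses.
    """
    n, p = X.shape
    shadows = X.copy()
    for j in range(p):
        shadows[:, j] = rng.permutation(shadows[:, j])
    augmented = np.hstack([X, shadows])
    model = model_cls(int(rng.integers(0, 2**31 - 1))).fit(augmented, y)
    importances = model.feature_importances_
    shadow_cutoff = importances[p:].max() if p else 0.0
    null_max = np.empty(cfg["n_tree_permutations"])
    for i in range(cfg["n_tree_permutations"]):
        perm_fit = model_cls(int(rng.integers(0, 2**31 - 1))).fit(
            augmented, rng.permutation(y)
        )
        null_max[i] = perm_fit.feature_importances_[:p].max()
    perm_cutoff = float(np.quantile(null_max, 1 - cfg["alpha"]))
    cutoff = max(shadow_cutoff, perm_cutoff)
    flags = {}
    for j, name in enumerate(names):
        if importances[j] > cutoff:
            rho = stats.spearmanr(X[:, j], y).statistic
            if np.isfinite(rho) and rho != 0:
                flags[name] = _sign(rho)
    return flags


def _method_rf(X, y, names, rng, cfg) -> dict[str, str]:
    cls = lambda random_state: RandomForestRegressor(  # noqa: E731
        n_estimators=cfg["n_trees"], random_state=random_state
    )
    return _shadow_importance_flags(cls, X, y, names, rng, cfg)


def _method_gbt(X, y, names, rng, cfg) -> dict[str, str]:
    cls = lambda random_state: GradientBoostingRegressor(  # noqa: E731
        n_estimators=cfg["n_trees"], random_state=random_state
    )
    return _shadow_importance_flags(cls, X, y, names, rng, cfg)


_METHOD_FUNCS = {
    "ols": _method_ols,
    "ridge": _method_ridge,
    "lasso": _method_lasso,
    "lars": _method_lars,
    "stepwise": _method_stepwise,
    "rf": _method_rf,
    "gbt": _method_gbt,
}


def associate(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    *,
    methods: Sequence[str] = ALL_METHODS,
    min_methods: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    n_permutations: int = 199,
    n_splits: int = 20,
    n_tree_permutations: int = 20,
    max_lars_terms: int = 3,
    n_trees: int = 100,
) -> list[AssociationResult]:
    """Identify predictors associated with performance via method consensus.

    ``design`` is a team x predictor matrix (rows aligned with ``responses``,
    a team x score matrix).  Predictors are standardised internally; constant
    predictors are dropped.  Every (predictor, response) pair flagged by at
    least one method yields an :class:`AssociationResult`; ``reported`` is
    true when at least ``min_methods`` methods agree with a consistent
    direction.  Deterministic given ``seed``.
    """
    if len(design) != len(responses):
        raise ValueError("design and responses must have the same rows (teams)")
    if len(design) < 8:
        raise ValueError("association analysis needs at least 8 teams")
    unknown = set(methods) - set(_METHOD_FUNCS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    cfg = {
        "alpha": alpha,
        "n_permutations": n_permutations,
        "n_splits": n_splits,
        "n_tree_permutations": n_tree_permutations,
        "max_lars_terms": max_lars_terms,
        "n_trees": n_trees,
    }
    X, names = _standardize(design)
    results: list[AssociationResult] = []
    master = np.random.default_rng(seed)
    for response_name in responses.columns:
        y = responses[response_name].astype(float).to_numpy()
        if np.ptp(y[np.isfinite(y)] if np.isfinite(y).any() else y) == 0 or not np.all(np.isfinite(y)):
            warnings.warn(f"response {response_name!r} is constant or non-finite; skipped",
                          stacklevel=2)
            continue
        y_std = (y - y.mean()) / y.std(ddof=0)
        flags_by_method: dict[str, dict[str, str]] = {}
        for method in methods:
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            flags_by_method[method] = _METHOD_FUNCS[method](X, y_std, names, rng, cfg)
        flagged = sorted({p for flags in flags_by_method.values() for p in flags})
        for predictor in flagged:
            votes = {m: flags[predictor] for m, flags in flags_by_method.items()
                     if predictor in flags}
            directions = set(votes.values())
            conflict = len(directions) > 1
            direction = votes[max(votes)] if conflict else next(iter(directions))
            results.append(
                AssociationResult(
                    predictor=predictor,
                    response=response_name,
                    direction=direction,
                    supporting_methods=len(votes),
                    method_flags=votes,
                    reported=(len(votes) >= min_methods) and not conflict,
                    conflict=conflict,
                )
            )
    return results
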