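"""Decomposition of utilization inequality into covariate contributions.

A probit with survey weights is fitted to the binary outcome; its partial
effects at the weighted covariate means define a linear approximation
y_i ~ alpha^m + sum_j beta^m_j x_ij + eps_i.  Because the concentration
index is linear in that approximation, the total index splits exactly into
per-covariate contributions elasticity_j * C_j plus a generalized-CI
residual term.  A weighted linear probability model is the documented
fallback when the probit cannot be fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from equicat.concentration import (
    CIEstimate,
    UndefinedIndexError,
    concentration_index,
    weighted_cov,
)
from equicat.living_standards import RankedDataset

logger = logging.getLogger("equicat")

NEED_GROUP = "need"
NON_NEED_GROUP = "non_need"
CONSUMPTION_GROUP = "consumption"

#: default need factors: age, gender, disability, chronic disease
DEFAULT_NEED = ["age_years", "male", "disability", "ncd"]

GOVERNORATE_REFERENCE = "greater_cairo"
EDUC_REFERENCE = "none_primary_prep"


def build_total_use(individuals: pd.DataFrame) -> pd.DataFrame:
    """OR-combine public/private indicators into total use per level of care."""
    out = pd.DataFrame(index=individuals.index)
    out["total_outpatient"] = (
        (individuals["use_out_public"] == 1) | (individuals["use_out_private"] == 1)
    ).astype(int)
    out["total_inpatient"] = (
        (individuals["use_inp_public"] == 1) | (individuals["use_inp_private"] == 1)
    ).astype(int)
    return out


def design_matrix(
    ranked: RankedDataset,
    *,
    need: list[str] | None = None,
    consumption: str = "log_eq_consumption",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Covariate matrix (no constant) and column -> group mapping.

    Need factors enter at actual values; non-need factors are the urban
    dummy, household size, education dummies (lowest level as reference),
    governorate dummies (Greater-Cairo reference), ordinal duration score,
    service knowledge and head's employment; living standards enter as the
    log of equivalized consumption.
    """
    df = ranked.data
    need = list(DEFAULT_NEED) if need is None else list(need)
    X = pd.DataFrame(index=df.index)
    groups: dict[str, str] = {}

    for col in need:
        if col not in df.columns:
            raise KeyError(f"need column {col!r} missing from dataset")
        X[col] = df[col].astype(float)
        groups[col] = NEED_GROUP

    X["urban"] = df["urban"].astype(float)
    X["hh_size"] = df["family_size"].astype(float)
    for lvl in ("secondary_technical", "university_plus"):
        name = f"educ_{lvl}"
        X[name] = (df["educ_head"] == lvl).astype(float)
    X["duration"] = df["duration_score"].astype(float)
    X["knowledge"] = df["knowledge"].astype(float)
    X["employed"] = df["employed_head"].astype(float)
    for gov in sorted(df["governorate"].unique()):
        if gov == GOVERNORATE_REFERENCE:
            continue
        X[f"gov_{gov}"] = (df["governorate"] == gov).astype(float)
    for col in X.columns:
        groups.setdefault(col, NON_NEED_GROUP)

    if consumption == "log_eq_consumption":
        X["log_eq_consumption"] = np.log(df["eq_consumption"].astype(float).clip(lower=1e-9))
        groups["log_eq_consumption"] = CONSUMPTION_GROUP
    elif consumption == "frac_rank":
        X["frac_rank"] = df["frac_rank"].astype(float)
        groups["frac_rank"] = CONSUMPTION_GROUP
    elif consumption != "none":
        raise ValueError(f"unknown consumption specification {consumption!r}")
    return X, groups


@dataclass
class PartialEffectsFit:
    """Probit (or LPM-fallback) fit summarized by partial effects at means."""

    marginal_effects: pd.Series  # beta^m_j, dy/dx at weighted covariate means
    mu: float  # weighted mean outcome
    xbar: pd.Series  # weighted covariate means
    method: str  # "probit" or "lpm"
    params: pd.Series = field(default=None, repr=False)  # underlying coefficients
    result: object = field(default=None, repr=False)

    @property
    def intercept_linear(self) -> float:
        # alpha^m of the linear approximation, chosen so the approximation
        # reproduces the weighted mean outcome exactly
        return self.mu - float(self.marginal_effects @ self.xbar.loc[self.marginal_effects.index])

    def linear_prediction(self, X: pd.DataFrame) -> np.ndarray:
        m = self.marginal_effects
        return self.intercept_linear + X[m.index].to_numpy(dtype=float) @ m.to_numpy()


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns by dropping one at a time
        bad = []
        for col in X.columns:
            sub = np.column_stack(
                [np.ones(len(X)), X.drop(columns=[col]).to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_partial_effects(
    y, X: pd.DataFrame, weights=None, *, method: str = "probit"
) -> PartialEffectsFit:
    """Weighted probit partial effects at means, with LPM fallback.

    ``method="lpm"`` requests the weighted linear probability model
    directly, in which case the partial effects are the WLS coefficients.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    _check_full_rank(X)
    wt = w / w.sum()
    xbar = pd.Series(wt @ X.to_numpy(dtype=float), index=X.columns)
    mu = float(wt @ y)
    exog = sm.add_constant(X.astype(float), has_constant="add")

    if method == "probit":
        try:
            model = sm.GLM(
                y,
                exog,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
                var_weights=w / w.mean(),
            )
            res = model.fit(maxiter=200)
            if not res.converged:
                raise RuntimeError("probit did not converge")
            theta = res.params
            eta_bar = float(theta["const"] + theta.drop("const") @ xbar)
            dens = float(np.exp(-0.5 * eta_bar**2) / np.sqrt(2.0 * np.pi))
            me = dens * theta.drop("const")
            return PartialEffectsFit(
                marginal_effects=me, mu=mu, xbar=xbar, method="probit",
                params=theta, result=res,
            )
        except Exception as exc:  # separation / convergence failure
            logger.warning("probit fit failed (%s); falling back to weighted LPM", exc)
            method = "lpm"
    if method != "lpm":
        raise ValueError(f"unknown method {method!r}")
    res = sm.WLS(y, exog, weights=w).fit()
    me = res.params.drop("const")
    return PartialEffectsFit(
        marginal_effects=me, mu=mu, xbar=xbar, method="lpm", params=res.params, result=res
    )


@dataclass
class DecompositionTable:
    """Per-covariate contributions to the concentration index."""

    table: pd.DataFrame  # elasticity, covariate_ci, contribution, pct_contribution, group
    ci: CIEstimate  # index of the outcome itself
    residual: float  # GC_eps / mu
    residual_gc: float  # same quantity via the generalized CI of residuals
    mu: float
    method: str

    @property
    def ci_plain(self) -> float:
        return self.ci.index_plain

    def group_contributions(self) -> pd.Series:
        return self.table.groupby("group")["contribution"].sum()


def decompose_ci(
    y,
    X: pd.DataFrame,
    weights,
    rank,
    *,
    groups: dict[str, str] | None = None,
    fit: PartialEffectsFit | None = None,
    method: str = "probit",
    outcome_name: str | None = None,
) -> DecompositionTable:
    """Split the outcome's CI into covariate contributions plus a residual.

    contribution_j = (beta^m_j * xbar_j / mu) * C_j computed as
    2*beta^m_j*Cov_w(x_j, R)/mu (robust to zero-mean covariates); the
    residual is CI - sum(contributions), cross-checked against the
    generalized CI of the linear-approximation residuals divided by mu.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    if fit is None:
        fit = fit_partial_effects(y, X, weights, method=method)
    mu = fit.mu
    if mu == 0:
        raise UndefinedIndexError("mu = 0: decomposition undefined")

    est = concentration_index(y, r, weights, outcome_name=outcome_name)
    rows = []
    for col in X.columns:
        beta = float(fit.marginal_effects[col])
        x = X[col].to_numpy(dtype=float)
        cov = weighted_cov(x, r, weights)
        contribution = 2.0 * beta * cov / mu
        xbar = float(fit.xbar[col])
        cov_ci = 2.0 * cov / xbar if xbar != 0 else np.nan
        rows.append(
            {
                "covariate": col,
                "group": (groups or {}).get(col, NON_NEED_GROUP),
                "marginal_effect": beta,
                "mean": xbar,
                "elasticity": beta * xbar / mu,
                "covariate_ci": cov_ci,
                "contribution": contribution,
                "pct_contribution": 100.0 * contribution / est.index_plain
                if est.index_plain != 0
                else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")

    residual = est.index_plain - float(table["contribution"].sum())
    eps = y - fit.linear_prediction(X)
    residual_gc = 2.0 * weighted_cov(eps, r, weights) / mu
    return DecompositionTable(
        table=table,
        ci=est,
        residual=residual,
        residual_gc=residual_gc,
        mu=mu,
        method=fit.method,
    )
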