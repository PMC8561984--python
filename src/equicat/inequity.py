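"""Indirect need-standardization of utilization and the horizontal inequity index.

Need-predicted use evaluates the fitted model with need factors at their
actual values and every non-need factor held at its weighted mean; the
need-standardized outcome is actual use minus that prediction plus the mean
prediction, which preserves the weighted mean exactly.  Horizontal inequity
is the concentration index of the standardized outcome, equivalently the
total CI minus the need contributions from the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from equicat.concentration import (
    CIEstimate,
    concentration_index,
    wagstaff_normalize,
    weighted_cov,
)
from equicat.decomposition import (
    NEED_GROUP,
    PartialEffectsFit,
    fit_partial_effects,
)


def need_predict(
    fit: PartialEffectsFit, X: pd.DataFrame, need_columns: list[str]
) -> np.ndarray:
    """Per-individual need-predicted use, non-need factors at weighted means.

    Uses the linear approximation implied by the partial effects at means:
    yhat^X_i = mu + sum_{j in need} beta^m_j (x_ij - xbar_j), whose weighted
    mean equals the outcome mean by construction.
    """
    missing = [c for c in need_columns if c not in X.columns]
    if missing:
        raise KeyError(f"need column(s) missing from design: {missing}")
    pred = np.full(len(X), fit.mu, dtype=float)
    for col in need_columns:
        beta = float(fit.marginal_effects[col])
        pred += beta * (X[col].to_numpy(dtype=float) - float(fit.xbar[col]))
    return pred


@dataclass
class StandardizedUse:
    """Actual, need-predicted and need-standardized use vectors."""

    need_predicted: np.ndarray
    standardized: np.ndarray  # y - yhat^X + mean(yhat); may leave [0, 1]
    mean_actual: float
    mean_standardized: float


def standardize_use(y, fit: PartialEffectsFit, X, need_columns, weights=None) -> StandardizedUse:
    """Indirectly standardize ``y`` for need. Mean is preserved exactly.

    The standardized variable is deliberately not clipped to [0, 1]:
    clipping would break both mean preservation and the additive identity
    with the decomposition.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    wt = w / w.sum()
    yhat_x = need_predict(fit, X, need_columns)
    # mean of predictions with all covariates at actual values; for the
    # linear approximation this equals the weighted outcome mean
    yhat_bar = float(wt @ fit.linear_prediction(X))
    standardized = y - yhat_x + yhat_bar
    return StandardizedUse(
        need_predicted=yhat_x,
        standardized=standardized,
        mean_actual=float(wt @ y),
        mean_standardized=float(wt @ standardized),
    )


@dataclass
class HIResult:
    """Horizontal inequity for one outcome."""

    hi_plain: float
    hi_wagstaff: float | None
    ci: CIEstimate  # CI of actual use
    need_ci: float  # CI of the need-predicted distribution (C_need_predicted)
    hi_via_contributions: float  # CI - sum of need contributions (route check)
    se: float
    mu: float
    method: str
    outcome_name: str | None = None

    @property
    def route_discrepancy(self) -> float:
        return abs(self.hi_plain - self.hi_via_contributions)


def horizontal_inequity(
    y,
    X: pd.DataFrame,
    weights,
    rank,
    *,
    need_columns: list[str] | None = None,
    groups: dict[str, str] | None = None,
    fit: PartialEffectsFit | None = None,
    method: str = "probit",
    outcome_name: str | None = None,
) -> HIResult:
    """HI = CI of need-standardized use, Wagstaff-normalized like the CI.

    ``need_columns`` defaults to every column mapped to the need group in
    ``groups``.  The second route (total CI minus need contributions) is
    computed alongside and exposed for the identity check.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    if need_columns is None:
        if groups is None:
            raise ValueError("need_columns or groups must be given")
        need_columns = [c for c, g in groups.items() if g == NEED_GROUP]
    if fit is None:
        fit = fit_partial_effects(y, X, weights, method=method)

    std = standardize_use(y, fit, X, need_columns, weights)
    est_actual = concentration_index(y, r, weights, outcome_name=outcome_name)
    mu = est_actual.mean_outcome

    hi_plain = 2.0 * weighted_cov(std.standardized, r, weights) / mu
    need_contrib = sum(
        2.0 * float(fit.marginal_effects[c]) * weighted_cov(X[c].to_numpy(dtype=float), r, weights) / mu
        for c in need_columns
    )
    hi_via = est_actual.index_plain - need_contrib
    need_ci_est = concentration_index(
        std.need_predicted, r, weights, outcome_name="need_predicted", compute_se=False
    )
    hi_wag = wagstaff_normalize(hi_plain, mu) if mu < 1 else None
    # standardized use shares y's covariance structure up to the smooth need
    # prediction; reuse the convenient-regression se on the standardized variable
    from equicat.concentration import ci_standard_error

    se = ci_standard_error(std.standardized, r, weights)
    return HIResult(
        hi_plain=float(hi_plain),
        hi_wagstaff=hi_wag,
        ci=est_actual,
        need_ci=float(need_ci_est.index_plain),
        hi_via_contributions=float(hi_via),
        se=float(se),
        mu=mu,
        method=fit.method,
        outcome_name=outcome_name,
    )
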