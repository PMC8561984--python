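"""Concentration indices with Wagstaff / Erreygers normalization.

The plain index is twice the weighted covariance between the outcome and
the fractional living-standards rank, divided by the outcome mean; negative
values mean the outcome is concentrated among the poor.  For binary
outcomes the attainable range depends on the mean, hence the Wagstaff
normalization CI/(1-mu) and the Erreygers correction (4*mu/(b-a))*CI.
Standard errors come from the weighted "convenient regression" of
2*var(R)*(y/mu) on the rank with a heteroskedasticity-robust sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

from equicat.living_standards import RankedDataset

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class UndefinedIndexError(ValueError):
    """The index is undefined (e.g. nobody uses the service: mu = 0)."""


def significance_stars(p_value: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p_value is None or np.isnan(p_value):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return ""


@dataclass
class CIEstimate:
    """A concentration-index estimate for one outcome."""

    index_plain: float
    index_wagstaff: float | None
    index_erreygers: float | None
    mean_outcome: float
    bounds: tuple[float, float]
    se: float
    n_eff: float
    outcome_name: str | None = None
    p_value: float = float("nan")
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _normalized(weights, n) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    return w / w.sum()


def weighted_cov(x, y, weights=None) -> float:
    """Weighted covariance, population convention (normalized weights)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wt = _normalized(weights, x.size)
    xm = float(wt @ x)
    ym = float(wt @ y)
    return float(wt @ ((x - xm) * (y - ym)))


def wagstaff_normalize(ci: float, mu: float) -> float:
    """Wagstaff normalization for a binary outcome: ci / (1 - mu)."""
    if not 0 <= mu < 1:
        raise ValueError("Wagstaff normalization needs 0 <= mu < 1")
    return ci / (1.0 - mu)


def erreygers_index(ci: float, mu: float, a: float = 0.0, b: float = 1.0) -> float:
    """Erreygers correction (4*mu/(b-a))*ci for an outcome bounded in [a, b]."""
    if b <= a:
        raise ValueError("need b > a")
    return 4.0 * mu * ci / (b - a)


def ci_standard_error(y, rank, weights=None) -> float:
    """Robust standard error of the plain CI via the convenient regression.

    Regresses t_i = 2*var_w(R)*(y_i/mu) on R_i with normalized weights; the
    slope equals the plain CI and its HC1 sandwich variance is returned as
    the standard error.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations for a standard error")
    wt = _normalized(weights, n)
    mu = float(wt @ y)
    if mu == 0:
        raise UndefinedIndexError("mu = 0: CI undefined")
    rbar = float(wt @ r)
    rc = r - rbar
    var_r = float(wt @ rc**2)
    if var_r <= 0:
        raise ValueError("degenerate rank variance")
    t = 2.0 * var_r * (y / mu)
    tbar = float(wt @ t)
    slope = float(wt @ (rc * t)) / var_r
    resid = (t - tbar) - slope * rc
    meat = float(np.sum((wt * rc * resid) ** 2))
    var_slope = meat / var_r**2 * n / (n - 2)
    return float(np.sqrt(var_slope))


def concentration_index(
    y,
    rank,
    weights=None,
    *,
    outcome_name: str | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
    compute_se: bool = True,
) -> CIEstimate:
    """Estimate the concentration index of ``y`` against the fractional rank.

    For binary y the Wagstaff-normalized and Erreygers-corrected indices are
    filled in as well (Wagstaff requires mu < 1).  Constant y yields a
    degenerate zero-index estimate with se = 0.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    if y.shape != r.shape:
        raise ValueError("y and rank must have equal length")
    wt = _normalized(weights, y.size)
    mu = float(wt @ y)
    if mu == 0:
        raise UndefinedIndexError(f"outcome {outcome_name!r}: mu = 0, CI undefined")
    plain = 2.0 * weighted_cov(y, r, weights) / mu

    is_binary = set(np.unique(y)) <= {0.0, 1.0}
    wag = err = None
    if is_binary:
        if mu < 1.0:
            wag = wagstaff_normalize(plain, mu)
        err = erreygers_index(plain, mu, *bounds)

    degenerate = bool(np.all(y == y[0]))
    if degenerate or not compute_se:
        se, p = 0.0, float("nan")
    else:
        se = ci_standard_error(y, r, weights)
        p = 2.0 * stats.norm.sf(abs(plain) / se) if se > 0 else float("nan")

    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    return CIEstimate(
        index_plain=float(plain),
        index_wagstaff=wag,
        index_erreygers=err,
        mean_outcome=mu,
        bounds=bounds,
        se=float(se),
        n_eff=n_eff,
        outcome_name=outcome_name,
        p_value=float(p),
        degenerate=degenerate,
    )


def quintile_use_table(ranked: RankedDataset, outcomes: list[str]) -> pd.DataFrame:
    """Weighted mean use per quintile plus CI estimates, one column per outcome.

    Mirrors the quintile-distribution report layout: rows q1..q5, the overall
    weighted mean, and the plain / Wagstaff / Erreygers indices with stars.
    """
    df = ranked.data
    w = ranked.weights
    out: dict[str, dict] = {}
    for name in outcomes:
        y = df[name].to_numpy(dtype=float)
        col: dict[str, float | str] = {}
        for q in range(1, 6):
            mask = df["quintile"].to_numpy() == q
            col[f"q{q}"] = (
                float(np.average(y[mask], weights=w[mask])) if mask.any() else np.nan
            )
        col["overall"] = float(np.average(y, weights=w))
        est = concentration_index(y, ranked.rank, w, outcome_name=name)
        col["ci_plain"] = est.index_plain
        col["ci_wagstaff"] = est.index_wagstaff if est.index_wagstaff is not None else np.nan
        col["ci_erreygers"] = est.index_erreygers if est.index_erreygers is not None else np.nan
        col["se"] = est.se
        col["stars"] = est.stars
        out[name] = col
    return pd.DataFrame(out)
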