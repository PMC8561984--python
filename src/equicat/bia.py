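"""Benefit incidence analysis of provider subsidies.

Unit costs are total programme spending per service divided by total units
delivered.  Gross benefit per person-service is alpha_k * q * c_k; net
benefit subtracts the out-of-pocket payment before annualization and is
floored at zero.  Quintile shares and benefit concentration indices follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from equicat.concentration import concentration_index
from equicat.living_standards import RankedDataset
from equicat.survey_io import CostLedger, INPATIENT_SERVICES, OUTPATIENT_SERVICES, SERVICES


def annualization_factor(recall_weeks: float = 4.0, weeks_per_year: float = 52.0) -> float:
    """Recall periods per year: 13 for a 4-week outpatient recall."""
    if recall_weeks <= 0:
        raise ValueError("recall_weeks must be > 0")
    return weeks_per_year / recall_weeks


#: default annualization: outpatient reported over 4 weeks, inpatient over 12 months
DEFAULT_ALPHA = {
    **{s: annualization_factor(4.0) for s in OUTPATIENT_SERVICES},
    **{s: 1.0 for s in INPATIENT_SERVICES},
}


def unit_costs(ledger: CostLedger) -> dict[str, float]:
    """c_k = total spending / total units per service; zero units is an error."""
    out = {}
    for name, entry in ledger.services.items():
        spending = float(entry["total_spending"])
        units = float(entry["total_units"])
        if spending > 0 and units <= 0:
            raise ValueError(f"{name}: positive spending with zero units")
        out[name] = spending / units if units > 0 else 0.0
    return out


def individual_benefits(
    ranked: RankedDataset,
    costs: dict[str, float] | CostLedger,
    alpha: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long per-person-per-service table of gross and net subsidy benefits.

    Quantity is 1 per positive use report (the survey records any-use, a
    lower bound on utilization).  Services absent from the cost map get
    c_k = 0, so unsubsidized private care never generates programme benefit.
    Net benefit = alpha * max(q*c - oop, 0); the zero floor replaces
    negative values where reported out-of-pocket exceeds the unit cost.
    """
    if isinstance(costs, CostLedger):
        costs = unit_costs(costs)
    alpha = dict(DEFAULT_ALPHA) if alpha is None else dict(alpha)
    df = ranked.data
    frames = []
    for svc in SERVICES:
        q = df[f"use_{svc}"].to_numpy(dtype=float)
        f = df[f"oop_{svc}"].to_numpy(dtype=float)
        if np.any(f < 0):
            raise ValueError(f"negative OOP for service {svc}")
        c = float(costs.get(svc, 0.0))
        a = float(alpha.get(svc, 1.0))
        gross = a * q * c
        net = a * np.maximum(q * c - f, 0.0) * (q > 0)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": df["person_id"].to_numpy(),
                    "service": svc,
                    "quantity": q,
                    "unit_cost": c,
                    "oop": f,
                    "gross_benefit": gross,
                    "net_benefit": net,
                    "quintile": df["quintile"].to_numpy(),
                    "frac_rank": df["frac_rank"].to_numpy(),
                    "weight": df["weight"].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def quintile_benefit_shares(amounts, quintiles, weights=None) -> pd.Series:
    """Weighted benefit totals per quintile as percentages summing to 100."""
    amounts = np.asarray(amounts, dtype=float)
    q = np.asarray(quintiles, dtype=int)
    w = np.ones_like(amounts) if weights is None else np.asarray(weights, dtype=float)
    totals = pd.Series(
        {k: float(np.sum(w[q == k] * amounts[q == k])) for k in range(1, 6)}
    )
    grand = totals.sum()
    if grand <= 0:
        warnings.warn("all-zero benefit column: shares undefined", stacklevel=2)
        return totals * np.nan
    return 100.0 * totals / grand


@dataclass
class BenefitTable:
    """Quintile benefit shares, totals and benefit CIs per service."""

    shares: pd.DataFrame  # rows q1..q5, columns (service, gross/net), %
    totals: pd.DataFrame  # weighted total benefit per (service, gross/net)
    ci: pd.DataFrame  # plain CI (continuous benefit) per (service, gross/net)
    subsidy_shares: pd.Series | None  # % of total programme spending per service


def benefit_shares(
    benefits: pd.DataFrame, ledger: CostLedger | None = None
) -> BenefitTable:
    """Aggregate a benefit table to quintile shares and benefit CIs."""
    shares: dict[tuple[str, str], pd.Series] = {}
    totals: dict[tuple[str, str], float] = {}
    cis: dict[tuple[str, str], float] = {}
    for svc, grp in benefits.groupby("service", sort=False):
        w = grp["weight"].to_numpy(dtype=float)
        for kind in ("gross_benefit", "net_benefit"):
            label = "gross" if kind == "gross_benefit" else "net"
            amounts = grp[kind].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shares[(svc, label)] = quintile_benefit_shares(
                    amounts, grp["quintile"].to_numpy(), w
                )
            totals[(svc, label)] = float(np.sum(w * amounts))
            if np.sum(w * amounts) > 0:
                est = concentration_index(
                    amounts, grp["frac_rank"].to_numpy(dtype=float), w,
                    outcome_name=f"{svc}_{label}", compute_se=False,
                )
                cis[(svc, label)] = est.index_plain
            else:
                cis[(svc, label)] = np.nan

    shares_df = pd.DataFrame(shares)
    shares_df.index = [f"q{k}" for k in range(1, 6)]
    shares_df.columns = pd.MultiIndex.from_tuples(shares_df.columns, names=["service", "benefit"])
    totals_df = pd.Series(totals).unstack()
    ci_df = pd.Series(cis).unstack()

    subsidy = None
    if ledger is not None:
        grand = ledger.total_spending()
        if grand > 0:
            subsidy = pd.Series(
                {k: 100.0 * float(v["total_spending"]) / grand for k, v in ledger.services.items()}
            )
    return BenefitTable(shares=shares_df, totals=totals_df, ci=ci_df, subsidy_shares=subsidy)
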