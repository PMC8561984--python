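"""Synthetic household-survey generator with known ground truth.

Emulates the statistical structure the estimators assume: governorate
strata, overdispersed household sizes, log-normal equivalized consumption
shared by household members, chronic-disease prevalence rising with age and
falling with living standards, binary utilization from per-service probit
models, and out-of-pocket payments drawn only for users.  Service means can
be pinned exactly in expectation by giving a ``mean`` target per service:
the probit intercept is then solved on the realized sample so the expected
utilization matches the target up to binomial noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from equicat.living_standards import DEFAULT_THETA, equivalize, fractional_rank
from equicat.survey_io import (
    AGE_GROUPS,
    CONSUMPTION_CLASSES,
    CostLedger,
    DURATION_LEVELS,
    EDUC_LEVELS,
    SERVICES,
    SurveyDataset,
    age_group_of,
    write_costs,
    write_survey,
)


class ConfigError(ValueError):
    """The synthetic configuration is infeasible."""


# age spans used to draw a continuous age within each band
_AGE_SPANS = {"0-5": (0.0, 6.0), "6-17": (6.0, 18.0), "18-34": (18.0, 35.0),
              "35-64": (35.0, 65.0), "65+": (65.0, 85.0)}

_DEFAULT_GOVERNORATE_SHARES = {
    "giza_6october": 0.285,
    "greater_cairo": 0.206,
    "alexandria": 0.116,
    "qalyubia": 0.116,
    "sharkia": 0.067,
    "damietta": 0.098,
    "other": 0.112,
}

_DEFAULT_AGE_SHARES = {"0-5": 0.095, "6-17": 0.323, "18-34": 0.316, "35-64": 0.247, "65+": 0.020}

# probit-scale slopes; per-service intercepts are solved to hit the `mean`
# target (the observed utilization margins) on the realized sample
_DEFAULT_UTILIZATION = {
    "out_public": {"mean": 0.13, "ncd": 1.00, "age10": 0.06, "female": 0.10,
                   "disability": 0.15, "rank": -0.15},
    "out_private": {"mean": 0.18, "ncd": 1.00, "age10": 0.06, "female": 0.15,
                    "disability": 0.15, "rank": 1.15},
    "inp_public": {"mean": 0.07, "ncd": 0.45, "age10": 0.04, "female": 0.25, "rank": 0.16},
    "inp_private": {"mean": 0.02, "ncd": 0.35, "age10": 0.03, "female": 0.20, "rank": 0.12},
}

# OOP as a fraction of a per-service reference cost, increasing in living
# standards via rank_slope; cap bounds OOP at cap * reference cost
_DEFAULT_OOP = {
    "out_public": {"mean_frac": 0.45, "rank_slope": -0.6, "cap": 1.5, "ref_cost": 10.0},
    "out_private": {"mean_frac": 0.90, "rank_slope": 0.3, "cap": 2.0, "ref_cost": 15.0},
    "inp_public": {"mean_frac": 0.20, "rank_slope": -0.4, "cap": 1.5, "ref_cost": 240.0},
    "inp_private": {"mean_frac": 0.80, "rank_slope": 0.2, "cap": 2.0, "ref_cost": 400.0},
}

# ledger split 28.6% outpatient / 71.4% inpatient programme spending
_DEFAULT_COSTS = {
    "out_public": {"total_spending": 286000.0, "total_units": 28600.0},
    "inp_public": {"total_spending": 714000.0, "total_units": 2975.0},
}

_CONSUMPTION_SPLIT = {"food": 0.42, "nonfood": 0.18, "durables": 0.10,
                      "housing": 0.18, "education": 0.06, "health": 0.06}


@dataclass
class SyntheticConfig:
    """Parameters of the generative model (defaults emulate the study margins)."""

    n_households: int = 507
    mean_household_size: float = 3.6
    sd_household_size: float = 2.2
    governorate_shares: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GOVERNORATE_SHARES)
    )
    age_group_shares: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AGE_SHARES))
    male_share: float = 0.52
    urban_share: float = 0.888
    educ_shares: tuple[float, float, float] = (0.689, 0.192, 0.119)
    employed_share: float = 0.526
    duration_shares: tuple[float, float, float, float] = (0.21, 0.07, 0.67, 0.05)
    knowledge_share: float = 0.70
    # log-normal parameters of *equivalized* consumption (USD/month); the
    # defaults put the person-weighted quintile means near 40..182
    consumption_location: float = 4.43
    consumption_scale: float = 0.55
    ncd_prevalence: float = 0.204
    ncd_age_slope: float = 0.04  # probit-scale slope on (age - mean age)
    ncd_rank_slope: float = -1.0  # probit-scale slope on (rank - 0.5)
    disability_prevalence: float = 0.034
    utilization_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_UTILIZATION.items()}
    )
    oop_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_OOP.items()}
    )
    costs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COSTS.items()}
    )
    theta: float = DEFAULT_THETA
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_households < 2:
            raise ConfigError("n_households must be >= 2")
        for name, shares in (
            ("governorate_shares", list(self.governorate_shares.values())),
            ("age_group_shares", list(self.age_group_shares.values())),
            ("educ_shares", list(self.educ_shares)),
            ("duration_shares", list(self.duration_shares)),
        ):
            if any(s < 0 for s in shares) or not math.isclose(sum(shares), 1.0, abs_tol=5e-3):
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        for p, name in (
            (self.ncd_prevalence, "ncd_prevalence"),
            (self.disability_prevalence, "disability_prevalence"),
            (self.male_share, "male_share"),
            (self.urban_share, "urban_share"),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.mean_household_size < 1:
            raise ConfigError("mean_household_size must be >= 1")
        if set(self.age_group_shares) != set(AGE_GROUPS):
            raise ConfigError(f"age_group_shares must cover {AGE_GROUPS}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("educ_shares", "duration_shares"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


def _normalized_shares(shares: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = list(shares)
    vals = np.asarray([shares[k] for k in keys], dtype=float)
    return keys, vals / vals.sum()


def _household_sizes(rng, n, mean, sd) -> np.ndarray:
    # shifted negative binomial: size = 1 + NB(m, r); supports mean/sd with
    # overdispersion and no zero-size households
    m = mean - 1.0
    var = sd * sd
    if m <= 0:
        return np.ones(n, dtype=int)
    if var <= m:  # under-dispersed target: fall back to Poisson
        return 1 + rng.poisson(m, size=n)
    r = m * m / (var - m)
    p = r / (r + m)
    return 1 + rng.negative_binomial(r, p, size=n)


def _solve_intercept(score: np.ndarray, target: float) -> float:
    """Intercept c with mean(Phi(c + score)) == target, by bisection."""
    if not 0 < target < 1:
        raise ConfigError("mean target must be in (0, 1)")
    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(stats.norm.cdf(mid + score))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _utilization_scores(coefs: dict[str, float], features: pd.DataFrame) -> np.ndarray:
    score = np.zeros(len(features))
    for key, value in coefs.items():
        if key in ("mean", "intercept"):
            continue
        if key not in features.columns:
            raise ConfigError(f"unknown utilization coefficient {key!r}")
        score += float(value) * features[key].to_numpy(dtype=float)
    return score


def _probit_draw(rng, coefs: dict[str, float], features: pd.DataFrame) -> np.ndarray:
    score = _utilization_scores(coefs, features)
    if "mean" in coefs:
        intercept = _solve_intercept(score, float(coefs["mean"]))
    else:
        intercept = float(coefs.get("intercept", 0.0))
    p = stats.norm.cdf(intercept + score)
    return (rng.random(len(p)) < p).astype(int)


def generate_survey(config: SyntheticConfig) -> SurveyDataset:
    """Draw a full survey from the generative model (reproducible by seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_hh = config.n_households

    gov_keys, gov_p = _normalized_shares(config.governorate_shares)
    governorate = rng.choice(gov_keys, size=n_hh, p=gov_p)
    sizes = _household_sizes(rng, n_hh, config.mean_household_size, config.sd_household_size)
    eq_cons = rng.lognormal(config.consumption_location, config.consumption_scale, size=n_hh)
    consumption_total = eq_cons * sizes.astype(float) ** config.theta

    split_keys = list(_CONSUMPTION_SPLIT)
    split = rng.dirichlet(40.0 * np.asarray([_CONSUMPTION_SPLIT[k] for k in split_keys]), size=n_hh)
    hh = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:05d}" for i in range(n_hh)],
            "family_size": sizes.astype(int),
            "urban": (rng.random(n_hh) < config.urban_share).astype(int),
            "governorate": governorate,
            "educ_head": rng.choice(EDUC_LEVELS, size=n_hh, p=np.asarray(config.educ_shares) / sum(config.educ_shares)),
            "employed_head": (rng.random(n_hh) < config.employed_share).astype(int),
            "duration_cat": rng.choice(DURATION_LEVELS, size=n_hh, p=np.asarray(config.duration_shares) / sum(config.duration_shares)),
            "knowledge": (rng.random(n_hh) < config.knowledge_share).astype(int),
            "weight": np.ones(n_hh),
        }
    )
    for j, key in enumerate(split_keys):
        hh[f"consumption_{key}"] = consumption_total * split[:, j]

    # individuals
    n_ind = int(sizes.sum())
    hh_index = np.repeat(np.arange(n_hh), sizes)
    age_keys, age_p = _normalized_shares(config.age_group_shares)
    bands = rng.choice(age_keys, size=n_ind, p=age_p)
    lo = np.asarray([_AGE_SPANS[b][0] for b in bands])
    hi = np.asarray([_AGE_SPANS[b][1] for b in bands])
    ages = lo + rng.random(n_ind) * (hi - lo)
    female = (rng.random(n_ind) >= config.male_share).astype(int)

    ind_eq = eq_cons[hh_index]
    rank = fractional_rank(ind_eq, np.ones(n_ind))

    ncd_score = config.ncd_age_slope * (ages - float(np.mean(ages))) + config.ncd_rank_slope * (
        rank - 0.5
    )
    ncd_p = stats.norm.cdf(_solve_intercept(ncd_score, config.ncd_prevalence) + ncd_score)
    ncd = (rng.random(n_ind) < ncd_p).astype(int)
    disability = (rng.random(n_ind) < config.disability_prevalence).astype(int)

    features = pd.DataFrame(
        {
            "age_years": ages,
            "age10": ages / 10.0,
            "female": female.astype(float),
            "male": 1.0 - female,
            "ncd": ncd.astype(float),
            "disability": disability.astype(float),
            "rank": rank,
            "urban": hh["urban"].to_numpy()[hh_index].astype(float),
            "hh_size": sizes[hh_index].astype(float),
            "duration": (np.asarray([DURATION_LEVELS.index(d) for d in hh["duration_cat"]]) + 1.0)[hh_index],
            "knowledge": hh["knowledge"].to_numpy()[hh_index].astype(float),
            "employed": hh["employed_head"].to_numpy()[hh_index].astype(float),
        }
    )

    ind = pd.DataFrame(
        {
            "person_id": [f"P{i + 1:06d}" for i in range(n_ind)],
            "household_id": hh["household_id"].to_numpy()[hh_index],
            "age_years": np.round(ages, 1),
            "gender": np.where(female == 1, "female", "male"),
            "disability": disability,
            "ncd": ncd,
        }
    )
    for svc in SERVICES:
        coefs = config.utilization_coefficients.get(svc, {"mean": 0.1})
        ind[f"use_{svc}"] = _probit_draw(rng, coefs, features)

    for svc in SERVICES:
        model = config.oop_model.get(svc, {})
        ref = float(model.get("ref_cost", 0.0))
        mean_frac = float(model.get("mean_frac", 0.0))
        slope = float(model.get("rank_slope", 0.0))
        cap = float(model.get("cap", 1.5))
        users = ind[f"use_{svc}"].to_numpy() == 1
        oop = np.zeros(n_ind)
        if ref > 0 and mean_frac > 0 and users.any():
            frac = np.clip(mean_frac * (1.0 + slope * (rank - 0.5)), 0.0, None)
            noise = rng.gamma(shape=2.0, scale=0.5, size=n_ind)
            oop = np.minimum(ref * frac * noise, cap * ref) * users
        ind[f"oop_{svc}"] = np.round(oop, 4)

    ind["age_group"] = age_group_of(ind["age_years"]).values
    ds = SurveyDataset(individuals=ind, households=hh, currency_rate=17.6)
    return ds.validate()


def synthetic_cost_ledger(config: SyntheticConfig) -> CostLedger:
    return CostLedger(services={k: dict(v) for k, v in config.costs.items()}).validate()


def write_synthetic(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write individuals.csv, households.csv, costs.yaml and population.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_survey(config)
    paths = {
        "individuals": outdir / "individuals.csv",
        "households": outdir / "households.csv",
        "costs": outdir / "costs.yaml",
        "population": outdir / "population.yaml",
    }
    write_survey(ds, paths["individuals"], paths["households"])
    write_costs(synthetic_cost_ledger(config), paths["costs"])
    keys, p = _normalized_shares(config.governorate_shares)
    with open(paths["population"], "w") as fh:
        yaml.safe_dump({k: float(round(100000 * s)) for k, s in zip(keys, p)}, fh, sort_keys=True)
    return paths


@dataclass
class MCEstimate:
    """Monte-Carlo estimate with its standard error."""

    value: float
    se: float
    n: int


def true_concentration_index(
    config: SyntheticConfig, service: str, n_mc: int, *, n_batches: int = 10
) -> MCEstimate:
    """Population CI of a service under the generative model, by simulation.

    Simulates ~n_mc individuals in ``n_batches`` independent replicates,
    computes the plain CI within each, and returns the batch mean with its
    Monte-Carlo standard error (se ~ 1/sqrt(n_mc)).
    """
    if service not in SERVICES and service not in ("total_outpatient", "total_inpatient"):
        raise ConfigError(f"unknown service {service!r}")
    per_batch_hh = max(int(math.ceil(n_mc / n_batches / config.mean_household_size)), 2)
    values = []
    for b in range(n_batches):
        cfg = replace(config, n_households=per_batch_hh, seed=config.seed + 100003 * (b + 1))
        ds = generate_survey(cfg)
        flat = ds.individual_table()
        eq = equivalize(flat["consumption_total"].to_numpy(), flat["family_size"].to_numpy(), config.theta)
        r = fractional_rank(eq, flat["weight"].to_numpy(dtype=float))
        if service == "total_outpatient":
            y = ((flat["use_out_public"] == 1) | (flat["use_out_private"] == 1)).astype(float)
        elif service == "total_inpatient":
            y = ((flat["use_inp_public"] == 1) | (flat["use_inp_private"] == 1)).astype(float)
        else:
            y = flat[f"use_{service}"].astype(float)
        mu = float(np.average(y, weights=flat["weight"]))
        if mu == 0:
            values.append(0.0)
            continue
        cov = float(np.average((y - mu) * (r - np.average(r, weights=flat["weight"])), weights=flat["weight"]))
        values.append(2.0 * cov / mu)
    values = np.asarray(values)
    se = float(values.std(ddof=1) / math.sqrt(n_batches))
    return MCEstimate(value=float(values.mean()), se=se, n=int(per_batch_hh * n_batches * config.mean_household_size))
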