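"""Survey data model, file I/O, post-stratification weights and design utilities.

The individual/household CSV schemas are documented in the README.  All
monetary amounts are carried in USD internally; EGP inputs are converted at
load using ``currency_rate`` (default 17.6 EGP per USD).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("equicat")

# ---------------------------------------------------------------------------
# canonical categorical levels and column layouts
# ---------------------------------------------------------------------------

AGE_GROUPS = ["0-5", "6-17", "18-34", "35-64", "65+"]
_AGE_BIN_EDGES = [0.0, 6.0, 18.0, 35.0, 65.0, math.inf]

GENDERS = ["male", "female"]
EDUC_LEVELS = ["none_primary_prep", "secondary_technical", "university_plus"]
DURATION_LEVELS = ["lt2y", "2_4y", "4_5y", "gt5y"]
DURATION_SCORE = {lvl: i + 1 for i, lvl in enumerate(DURATION_LEVELS)}

SERVICES = ["out_public", "out_private", "inp_public", "inp_private"]
OUTPATIENT_SERVICES = ["out_public", "out_private"]
INPATIENT_SERVICES = ["inp_public", "inp_private"]
USE_COLUMNS = [f"use_{s}" for s in SERVICES]
OOP_COLUMNS = [f"oop_{s}" for s in SERVICES]

CONSUMPTION_CLASSES = ["food", "nonfood", "durables", "housing", "education", "health"]
CONSUMPTION_COLUMNS = [f"consumption_{c}" for c in CONSUMPTION_CLASSES]

INDIVIDUAL_COLUMNS = (
    ["person_id", "household_id", "age_years", "gender", "disability", "ncd"]
    + USE_COLUMNS
    + OOP_COLUMNS
)
HOUSEHOLD_COLUMNS = (
    ["household_id", "family_size"]
    + CONSUMPTION_COLUMNS
    + ["urban", "governorate", "educ_head", "employed_head", "duration_cat", "knowledge", "weight"]
)

_INDIVIDUAL_BINARY = ["disability", "ncd"] + USE_COLUMNS
_HOUSEHOLD_BINARY = ["urban", "employed_head"]


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class IntegrityError(ValueError):
    """Referential integrity between individuals and households is broken."""


def age_group_of(age_years) -> pd.Series:
    """Map ages in years onto the canonical five age bands."""
    age = pd.Series(np.asarray(age_years, dtype=float))
    if (age < 0).any():
        raise ValueError("age_years must be non-negative")
    idx = np.digitize(age, _AGE_BIN_EDGES[1:-1], right=False)
    return pd.Series(pd.Categorical.from_codes(idx, categories=AGE_GROUPS))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SurveyDataset:
    """Individual records joined to household attributes plus metadata.

    ``individuals`` and ``households`` are DataFrames following the schemas
    in :data:`INDIVIDUAL_COLUMNS` / :data:`HOUSEHOLD_COLUMNS` (individuals
    additionally carry a derived ``age_group`` column).
    """

    individuals: pd.DataFrame
    households: pd.DataFrame
    currency_rate: float = 17.6

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_households(self) -> int:
        return len(self.households)

    def validate(self) -> "SurveyDataset":
        _check_columns(self.individuals, INDIVIDUAL_COLUMNS, "individuals")
        _check_columns(self.households, HOUSEHOLD_COLUMNS, "households")
        ind, hh = self.individuals, self.households

        if ind["person_id"].duplicated().any():
            dup = ind.loc[ind["person_id"].duplicated(), "person_id"].iloc[0]
            raise IntegrityError(f"duplicate person_id {dup!r}")
        if hh["household_id"].duplicated().any():
            dup = hh.loc[hh["household_id"].duplicated(), "household_id"].iloc[0]
            raise IntegrityError(f"duplicate household_id {dup!r}")

        known = set(hh["household_id"])
        orphans = set(ind["household_id"]) - known
        if orphans:
            raise IntegrityError(
                f"individuals reference unknown household_id(s): {sorted(orphans)[:5]}"
            )

        for col in _INDIVIDUAL_BINARY:
            _check_binary(ind[col], col)
        for col in _HOUSEHOLD_BINARY:
            _check_binary(hh[col], col)

        if (hh["weight"] <= 0).any():
            raise ValueError("household weight must be > 0")
        if (hh["family_size"] < 1).any():
            raise ValueError("family_size must be >= 1")
        for col in CONSUMPTION_COLUMNS:
            if (hh[col] < 0).any():
                raise ValueError(f"{col} must be >= 0")

        sizes = ind.groupby("household_id").size()
        declared = hh.set_index("household_id")["family_size"]
        mismatch = declared.loc[sizes.index] != sizes
        if mismatch.any():
            bad = mismatch[mismatch].index[0]
            raise IntegrityError(
                f"family_size of household {bad!r} does not match its member count"
            )

        for svc in SERVICES:
            oop, use = ind[f"oop_{svc}"], ind[f"use_{svc}"]
            if (oop < 0).any():
                raise ValueError(f"oop_{svc} must be >= 0")
            if ((oop > 0) & (use == 0)).any():
                raise ValueError(f"oop_{svc} positive while use_{svc} is 0")
        return self

    def individual_table(self) -> pd.DataFrame:
        """Flat individual-level frame with household attributes merged in.

        Adds ``consumption_total`` (sum of the expenditure classes),
        ``duration_score`` (ordinal 1-4), and dummy columns ``male`` /
        ``female``.  Household ``weight`` is inherited by every member.
        """
        hh = self.households.copy()
        hh["consumption_total"] = hh[CONSUMPTION_COLUMNS].sum(axis=1)
        hh["duration_score"] = hh["duration_cat"].map(DURATION_SCORE).astype(float)
        out = self.individuals.merge(hh, on="household_id", how="left", validate="m:1")
        out["male"] = (out["gender"] == "male").astype(int)
        out["female"] = (out["gender"] == "female").astype(int)
        return out


@dataclass
class CostLedger:
    """Total provider spending and units delivered per subsidized service."""

    services: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> "CostLedger":
        for name, entry in self.services.items():
            spending = float(entry["total_spending"])
            units = float(entry["total_units"])
            if spending < 0:
                raise ValueError(f"{name}: total_spending must be >= 0")
            if spending > 0 and units <= 0:
                raise ValueError(f"{name}: positive spending requires total_units > 0")
        return self

    def total_spending(self) -> float:
        return sum(float(e["total_spending"]) for e in self.services.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _check_binary(series: pd.Series, name: str) -> None:
    vals = set(pd.unique(series.dropna()))
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError(f"column {name!r} must be binary 0/1, got values {sorted(vals)[:5]}")


def _canonicalize_level(series: pd.Series, levels, name: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = set(s.unique()) - set(levels)
    if bad:
        raise ValueError(f"column {name!r}: unknown level(s) {sorted(bad)}; expected {levels}")
    return s


def read_survey(
    individual_file,
    household_file,
    *,
    currency: str = "USD",
    currency_rate: float = 17.6,
) -> SurveyDataset:
    """Load and validate the two survey CSVs into a :class:`SurveyDataset`.

    ``currency="EGP"`` divides every monetary column by ``currency_rate``
    so all downstream analysis runs in USD.
    """
    ind = pd.read_csv(individual_file)
    hh = pd.read_csv(household_file)
    _check_columns(ind, INDIVIDUAL_COLUMNS, "individuals")
    _check_columns(hh, HOUSEHOLD_COLUMNS, "households")

    ind = ind.copy()
    hh = hh.copy()
    ind["gender"] = _canonicalize_level(ind["gender"], GENDERS, "gender")
    hh["educ_head"] = _canonicalize_level(hh["educ_head"], EDUC_LEVELS, "educ_head")
    hh["duration_cat"] = _canonicalize_level(hh["duration_cat"], DURATION_LEVELS, "duration_cat")
    hh["governorate"] = hh["governorate"].astype(str).str.strip().str.lower()

    for col in _INDIVIDUAL_BINARY:
        _check_binary(ind[col], col)
        ind[col] = ind[col].astype(int)
    for col in _HOUSEHOLD_BINARY:
        _check_binary(hh[col], col)
        hh[col] = hh[col].astype(int)

    # missing OOP with positive use is read as "none reported"
    for svc in SERVICES:
        oop = f"oop_{svc}"
        n_missing = int((ind[oop].isna() & (ind[f"use_{svc}"] == 1)).sum())
        if n_missing:
            logger.warning("%d user(s) with missing %s treated as 0", n_missing, oop)
        ind[oop] = ind[oop].fillna(0.0).astype(float)

    if currency.upper() == "EGP":
        ind[OOP_COLUMNS] = ind[OOP_COLUMNS] / currency_rate
        hh[CONSUMPTION_COLUMNS] = hh[CONSUMPTION_COLUMNS] / currency_rate
    elif currency.upper() != "USD":
        raise ValueError(f"unsupported currency {currency!r}")

    ind["age_group"] = age_group_of(ind["age_years"]).values
    ds = SurveyDataset(individuals=ind, households=hh, currency_rate=currency_rate)
    return ds.validate()


def write_survey(dataset: SurveyDataset, individual_file, household_file) -> None:
    """Write the dataset back to the canonical CSV schema (USD amounts)."""
    ind = dataset.individuals[INDIVIDUAL_COLUMNS]
    hh = dataset.households[HOUSEHOLD_COLUMNS]
    ind.to_csv(individual_file, index=False, float_format="%.6f")
    hh.to_csv(household_file, index=False, float_format="%.6f")


def read_costs(path) -> CostLedger:
    """Load the per-service cost ledger from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("costs file must map service -> {total_spending, total_units}")
    services = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict) or not {"total_spending", "total_units"} <= set(entry):
            raise SchemaError(f"costs entry {name!r} needs total_spending and total_units")
        services[name] = {
            "total_spending": float(entry["total_spending"]),
            "total_units": float(entry["total_units"]),
        }
    return CostLedger(services=services).validate()


def write_costs(ledger: CostLedger, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ledger.services, fh, sort_keys=True)


def read_population(path) -> dict[str, float]:
    """Load the governorate -> population map from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("population file must map governorate -> count")
    return {str(k).strip().lower(): float(v) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# weights and design utilities
# ---------------------------------------------------------------------------


def build_weights(
    dataset: SurveyDataset, population_by_stratum: dict[str, float]
) -> SurveyDataset:
    """Post-stratification weights from governorate population counts.

    Household weight = (stratum population share) / (stratum sample share),
    rescaled so weights sum to the number of households (mean weight 1).
    Members inherit the household weight wherever individual-level analysis
    needs one.  Sampled strata absent from the population map are an error;
    strata with population but no sampled household trigger a warning (their
    weight is undefined and the remaining shares are renormalized).
    """
    hh = dataset.households.copy()
    strata = hh["governorate"].astype(str).str.strip().str.lower()
    pop = {str(k).strip().lower(): float(v) for k, v in population_by_stratum.items()}

    missing = set(strata.unique()) - set(pop)
    if missing:
        raise ValueError(f"population map missing sampled stratum(s): {sorted(missing)}")

    unsampled = {g for g, p in pop.items() if p > 0 and g not in set(strata.unique())}
    if unsampled:
        warnings.warn(
            f"stratum(s) {sorted(unsampled)} have population but no sampled households; "
            "their weight is undefined",
            stacklevel=2,
        )
        pop = {g: p for g, p in pop.items() if g not in unsampled}

    pop_total = sum(pop.values())
    sample_counts = strata.value_counts()
    n = len(hh)
    pop_share = strata.map(lambda g: pop[g] / pop_total)
    sample_share = strata.map(sample_counts) / n
    w = pop_share / sample_share
    w = w * n / w.sum()
    hh["weight"] = w.astype(float)
    return replace(dataset, households=hh)


def required_sample_size(
    p: float, rel_precision: float, alpha: float, *, rounding: str = "nearest"
) -> int:
    """Minimum n to estimate a proportion ``p`` at relative precision.

    n = z^2 p(1-p) / d^2 with d = rel_precision * p and z the two-sided
    normal quantile at ``alpha``.  ``rounding`` is ``"nearest"`` (half-up,
    the convention under which p=0.5, 10% precision, alpha=0.05 gives the
    conventional 384) or ``"ceil"``.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if rel_precision <= 0:
        raise ValueError("rel_precision must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    d = rel_precision * p
    raw = z * z * p * (1 - p) / (d * d)
    if rounding == "nearest":
        n = math.floor(raw + 0.5)
    elif rounding == "ceil":
        n = math.ceil(raw)
    else:
        raise ValueError("rounding must be 'nearest' or 'ceil'")
    return max(int(n), 1)
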