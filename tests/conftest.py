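import numpy as np
import pandas as pd
import pytest

from equicat.survey_io import (
    CONSUMPTION_COLUMNS,
    SERVICES,
    SurveyDataset,
    age_group_of,
)


def make_individuals(rows):
    """Build an individuals frame from dicts with sparse overrides."""
    base = {
        "age_years": 30.0,
        "gender": "female",
        "disability": 0,
        "ncd": 0,
        **{f"use_{s}": 0 for s in SERVICES},
        **{f"oop_{s}": 0.0 for s in SERVICES},
    }
    recs = []
    for i, row in enumerate(rows):
        rec = {"person_id": f"P{i + 1}", **base, **row}
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["age_group"] = age_group_of(df["age_years"]).values
    return df


def make_households(rows):
    base = {
        "family_size": 1,
        **{c: 0.0 for c in CONSUMPTION_COLUMNS},
        "consumption_food": 100.0,
        "urban": 1,
        "governorate": "greater_cairo",
        "educ_head": "none_primary_prep",
        "employed_head": 1,
        "duration_cat": "4_5y",
        "knowledge": 1,
        "weight": 1.0,
    }
    return pd.DataFrame([{**base, **row} for row in rows])


def make_dataset(ind_rows, hh_rows) -> SurveyDataset:
    return SurveyDataset(
        individuals=make_individuals(ind_rows), households=make_households(hh_rows)
    ).validate()


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """2 households, 5 individuals, distinct consumption levels."""
    ind = [
        {"household_id": "H1", "age_years": 40, "use_out_public": 1, "oop_out_public": 3.0},
        {"household_id": "H1", "age_years": 8},
        {"household_id": "H1", "age_years": 3, "ncd": 1},
        {"household_id": "H2", "age_years": 70, "use_inp_public": 1},
        {"household_id": "H2", "age_years": 66, "gender": "male"},
    ]
    hh = [
        {"household_id": "H1", "family_size": 3, "consumption_food": 200.0},
        {"household_id": "H2", "family_size": 2, "consumption_food": 500.0,
         "governorate": "alexandria", "urban": 0},
    ]
    return make_dataset(ind, hh)


@pytest.fixture(scope="session")
def default_survey():
    """Default-config synthetic survey (507 households), shared across tests."""
    from equicat.synthetic_data import SyntheticConfig, generate_survey

    return generate_survey(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_ranked(default_survey):
    from equicat.decomposition import build_total_use
    from equicat.living_standards import rank_dataset

    ranked = rank_dataset(default_survey)
    totals = build_total_use(ranked.data)
    ranked.data["total_outpatient"] = totals["total_outpatient"]
    ranked.data["total_inpatient"] = totals["total_inpatient"]
    return ranked


@pytest.fixture(scope="session")
def big_ranked():
    """Larger synthetic survey (~7000 individuals) for recovery checks."""
    from equicat.decomposition import build_total_use
    from equicat.living_standards import rank_dataset
    from equicat.synthetic_data import SyntheticConfig, generate_survey

    ds = generate_survey(SyntheticConfig(n_households=2000, seed=7))
    ranked = rank_dataset(ds)
    totals = build_total_use(ranked.data)
    ranked.data["total_outpatient"] = totals["total_outpatient"]
    ranked.data["total_inpatient"] = totals["total_inpatient"]
    return ranked


def brute_force_ci(y, x, weights=None):
    """O(n^2) pairwise-sign oracle for the plain concentration index.

    CI = (1 / (2 mu)) * sum_ij wt_i wt_j (y_i - y_j) sgn(x_i - x_j), an
    independent route that never forms fractional ranks.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    wt = w / w.sum()
    mu = float(wt @ y)
    total = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            total += wt[i] * wt[j] * (y[i] - y[j]) * np.sign(x[i] - x[j])
    return total / (2.0 * mu)
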