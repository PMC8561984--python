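"""Equivalized consumption, weighted fractional ranks and quintiles.

This is the ranking backbone shared by every index: each individual carries
the household's equivalized consumption, is ranked by the weighted midpoint
rule (mean rank exactly 0.5), and is placed into person-weighted quintiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from equicat.survey_io import SurveyDataset

DEFAULT_THETA = 0.56


def equivalize(consumption_total, family_size, theta: float = DEFAULT_THETA):
    """Adult-equivalent consumption: total / family_size ** theta.

    ``theta=1`` reduces to per-capita consumption.  Accepts scalars or
    arrays; homogeneous of degree 1 in consumption.
    """
    cons = np.asarray(consumption_total, dtype=float)
    size = np.asarray(family_size, dtype=float)
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    if np.any(size < 1):
        raise ValueError("family_size must be >= 1")
    if np.any(cons < 0):
        raise ValueError("consumption_total must be >= 0")
    out = cons / size**theta
    return float(out) if out.ndim == 0 else out


def fractional_rank(values, weights=None) -> np.ndarray:
    """Weighted fractional rank R_i in (0, 1), poorest first.

    R_i = (cumulative weight of strictly poorer observations + half the
    pooled weight of the observation's tie block) / total weight.  Tied
    values share the midpoint rank of their pooled block, which keeps the
    weighted mean rank at exactly 0.5.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("fractional_rank of empty input is undefined")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    uniq, inverse = np.unique(v, return_inverse=True)
    block_w = np.bincount(inverse, weights=w, minlength=uniq.size)
    cum = np.cumsum(block_w)
    rank_u = (cum - block_w / 2.0) / cum[-1]
    return rank_u[inverse]


def _stable_midpoint_positions(values, weights) -> np.ndarray:
    # tie-broken (stable sort order) midpoint cumulative positions; used for
    # quintile assignment so equal-weight ties still split 20/20/20/20/20
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    sw = w[order]
    cum = np.cumsum(sw)
    pos_sorted = (cum - sw / 2.0) / cum[-1]
    pos = np.empty_like(pos_sorted)
    pos[order] = pos_sorted
    return pos


def assign_quintiles(values, weights=None) -> np.ndarray:
    """Person-weighted quintile (1..5) from weighted cumulative shares.

    Boundaries are the weighted cumulative population shares 0.2..0.8;
    observation i falls in the smallest q with its midpoint cumulative
    position <= q/5.  Ties are split in stable input order so each quintile
    holds 20% of the weight up to the granularity of a single observation.
    """
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    pos = _stable_midpoint_positions(v, w)
    q = np.minimum(np.ceil(pos * 5.0).astype(int), 5)
    return np.maximum(q, 1)


@dataclass
class RankedDataset:
    """Individual-level table augmented with the living-standards ranking.

    ``data`` is the flat individual frame from
    :meth:`SurveyDataset.individual_table` plus ``eq_consumption``,
    ``frac_rank`` and ``quintile`` columns.
    """

    data: pd.DataFrame
    theta: float = DEFAULT_THETA

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    @property
    def rank(self) -> np.ndarray:
        return self.data["frac_rank"].to_numpy(dtype=float)


def rank_dataset(dataset: SurveyDataset, theta: float = DEFAULT_THETA) -> RankedDataset:
    """Build the ranked individual-level table from a validated survey."""
    flat = dataset.individual_table()
    if "consumption_total" not in flat.columns:
        raise KeyError("consumption_total missing; cannot rank the dataset")
    flat = flat.copy()
    flat["eq_consumption"] = equivalize(
        flat["consumption_total"].to_numpy(), flat["family_size"].to_numpy(), theta
    )
    w = flat["weight"].to_numpy(dtype=float)
    flat["frac_rank"] = fractional_rank(flat["eq_consumption"].to_numpy(), w)
    flat["quintile"] = assign_quintiles(flat["eq_consumption"].to_numpy(), w)
    return RankedDataset(data=flat, theta=theta)
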