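"""Reactivation statistics: labeling fractions, chance overlap, and BH-FDR.

Reactivation of a learning-tagged ensemble during retrieval is quantified per
animal and region as the fraction of double-labeled cells relative to the
overlap expected if the learning tag (Td+) and the retrieval marker (c-Fos+)
were independent:

    chance_pct = (Td+/DAPI+) * (c-Fos+/DAPI+) * 100
    ratio      = double_pct / chance_pct

A ratio of 1 is chance-level reactivation; above 1, the retrieval-active
population is enriched for learning-tagged cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UndefinedResultError, ValidationError, validate_counts

logger = logging.getLogger(__name__)

REACTIVATION_COLUMNS = [
    "animal_id",
    "group",
    "region",
    "td_pct",
    "cfos_pct",
    "double_pct",
    "chance_pct",
    "ratio",
]


def label_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent of DAPI+ cells that are Td+, c-Fos+, and double-labeled.

    Raises :class:`UndefinedResultError` for any row with ``n_dapi == 0``.
    """
    counts = validate_counts(counts)
    if (counts["n_dapi"] == 0).any():
        row = counts.index[counts["n_dapi"] == 0][0]
        raise UndefinedResultError(f"row {row}: fractions undefined, n_dapi is 0")
    out = counts.copy()
    dapi = counts["n_dapi"].astype(float)
    out["td_pct"] = 100.0 * counts["n_td"] / dapi
    out["cfos_pct"] = 100.0 * counts["n_cfos"] / dapi
    out["double_pct"] = 100.0 * counts["n_double"] / dapi
    return out


def chance_overlap_pct(td_pct, cfos_pct):
    """Expected double-labeled percent under independence of the two labels.

    chance = (td_pct/100) * (cfos_pct/100) * 100, i.e. the product of the two
    labeling fractions expressed as a percent of DAPI+ cells.
    """
    td = np.asarray(td_pct, dtype=float)
    cf = np.asarray(cfos_pct, dtype=float)
    if ((td < 0) | (td > 100)).any() or ((cf < 0) | (cf > 100)).any():
        raise ValidationError("labeling percentages must lie in [0, 100]")
    out = td * cf / 100.0
    return float(out) if out.ndim == 0 else out


def reactivation_ratio(double_pct, chance_pct):
    """Observed/chance double-labeling ratio; 1 = chance-level reactivation.

    When chance is 0 and the observed overlap is also 0 the ratio is undefined
    and returned as NaN (flagged downstream); a positive overlap at zero chance
    is contradictory and raises.
    """
    dbl = np.asarray(double_pct, dtype=float)
    ch = np.asarray(chance_pct, dtype=float)
    if (ch < 0).any():
        raise ValidationError("chance percentage must be non-negative")
    if ((ch == 0) & (dbl > 0)).any():
        raise UndefinedResultError("positive double-labeling at zero chance level")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ch == 0, np.nan, dbl / np.where(ch == 0, 1.0, ch))
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def reactivation_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Full per-animal, per-region reactivation table from raw counts."""
    out = label_fractions(counts)
    out["chance_pct"] = chance_overlap_pct(out["td_pct"].values, out["cfos_pct"].values)
    out["ratio"] = reactivation_ratio(out["double_pct"].values, out["chance_pct"].values)
    n_undef = int(np.isnan(out["ratio"]).sum())
    if n_undef:
        logger.info("reactivation ratio undefined (chance 0) for %d rows; left missing", n_undef)
    return out[REACTIVATION_COLUMNS]


def group_region_summary(react: pd.DataFrame, value: str = "ratio") -> pd.DataFrame:
    """Mean, standard error, and n per group x region, excluding missing values."""
    n_missing = int(react[value].isna().sum())
    if n_missing:
        logger.info("excluding %d missing %s values from group summaries", n_missing, value)
    g = react.dropna(subset=[value]).groupby(["group", "region"], sort=False)[value]
    out = g.agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
    return out.reset_index()


@dataclass
class AdjustedPValueSet:
    """One global Benjamini-Hochberg family.

    ``raw_product`` is the plain p * m / rank product; ``adj_p`` additionally
    applies the step-up running-minimum so adjusted values are monotone in the
    raw p-values (the standard procedure; the plain product alone can be
    non-monotone).
    """

    labels: list
    raw_p: np.ndarray
    rank: np.ndarray
    raw_product: np.ndarray
    adj_p: np.ndarray
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "raw_p": self.raw_p,
                "rank": self.rank,
                "raw_product": self.raw_product,
                "adj_p": self.adj_p,
            }
        )


def bh_adjust(raw_p, labels=None) -> AdjustedPValueSet:
    """Benjamini-Hochberg step-up adjustment of one global family of p-values.

    Each p-value is multiplied by the family size and divided by its ascending
    rank; a running minimum from the largest rank downward enforces
    monotonicity and values are capped at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-value family must be a non-empty 1-d collection")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks_sorted = np.arange(1, m + 1)
    product_sorted = p[order] * m / ranks_sorted
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(product_sorted[::-1])[::-1])

    rank = np.empty(m, dtype=int)
    rank[order] = ranks_sorted
    raw_product = np.empty(m)
    raw_product[order] = product_sorted
    adj = np.empty(m)
    adj[order] = adj_sorted

    if labels is None:
        labels = list(range(m))
    elif len(labels) != m:
        raise ValidationError("labels length must match the p-value family size")
    return AdjustedPValueSet(
        labels=list(labels),
        raw_p=p,
        rank=rank,
        raw_product=np.minimum(1.0, raw_product),
        adj_p=adj,
        m=m,
    )
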