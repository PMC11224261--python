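"""Loading and validation of tagged-cell count tables and behavioral indices.

Counts are one row per animal x region: total cells (DAPI+), learning-tagged
cells (Td+), retrieval-active cells (c-Fos+), and double-labeled cells
(Td+ and c-Fos+). Per-image rows (several rows for the same animal x region,
e.g. one per bilateral image) are accepted and summed with a warning, since
the unit of analysis for across-animal correlations is the animal x region
total.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["animal_id", "group", "region", "n_dapi", "n_td", "n_cfos", "n_double"]
_COUNT_FIELDS = ["n_dapi", "n_td", "n_cfos", "n_double"]
METADATA_COLUMNS = ["region", "anatomical_group"]
ANATOMICAL_GROUPS = ("mPFC", "amygdala", "hippocampus", "PH")

# 15-region panel of the study design this package emulates: medial prefrontal
# cortex, amygdala nuclei, dorsal/ventral hippocampus, and the parahippocampal
# area (perirhinal cortices + ventral subiculum).
DEFAULT_REGIONS: dict[str, str] = {
    "AC": "mPFC",
    "PL": "mPFC",
    "IL": "mPFC",
    "BLA": "amygdala",
    "BMA": "amygdala",
    "CEA": "amygdala",
    "LA": "amygdala",
    "MEA": "amygdala",
    "dCA1": "hippocampus",
    "dDG": "hippocampus",
    "vCA1": "hippocampus",
    "vDG": "hippocampus",
    "vSUB": "PH",
    "PER_35": "PH",
    "PER_36": "PH",
}


class SchemaError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class ValidationError(ValueError):
    """A row violates a count invariant or referential integrity."""


class UndefinedResultError(ValueError):
    """An index is mathematically undefined for the given inputs (e.g. 0/0)."""


def default_region_metadata() -> pd.DataFrame:
    """Region metadata for the default 15-region panel."""
    return pd.DataFrame(
        {"region": list(DEFAULT_REGIONS), "anatomical_group": list(DEFAULT_REGIONS.values())}
    )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def validate_counts(counts: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate count invariants row by row; returns the (typed) frame.

    Raises :class:`ValidationError` naming the first offending row and field.
    """
    _require_columns(counts, COUNT_COLUMNS, "counts table")
    counts = counts.copy()
    for col in _COUNT_FIELDS:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = counts.index[vals.isna()][0]
            raise ValidationError(f"row {row}: field {col} is not numeric")
        if (vals < 0).any():
            row = counts.index[vals < 0][0]
            raise ValidationError(f"row {row}: field {col} is negative")
        if (vals % 1 != 0).any():
            row = counts.index[vals % 1 != 0][0]
            raise ValidationError(f"row {row}: field {col} is not an integer count")
        counts[col] = vals.astype(np.int64)

    for col, bound in (("n_td", "n_dapi"), ("n_cfos", "n_dapi")):
        bad = counts[col] > counts[bound]
        if bad.any():
            row = counts.index[bad][0]
            raise ValidationError(f"row {row}: field {col} exceeds {bound}")
    bad = counts["n_double"] > counts[["n_td", "n_cfos"]].min(axis=1)
    if bad.any():
        row = counts.index[bad][0]
        raise ValidationError(f"row {row}: field n_double exceeds min(n_td, n_cfos)")

    if metadata is not None:
        _require_columns(metadata, METADATA_COLUMNS, "region metadata")
        if metadata["region"].duplicated().any():
            dup = metadata.loc[metadata["region"].duplicated(), "region"].iloc[0]
            raise ValidationError(f"region metadata lists region {dup!r} more than once")
        known = set(metadata["region"])
        unknown = ~counts["region"].isin(known)
        if unknown.any():
            row = counts.index[unknown][0]
            raise ValidationError(
                f"row {row}: field region {counts.loc[row, 'region']!r} absent from metadata"
            )
    return counts


def aggregate_per_image(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-image rows to one row per animal x region."""
    keys = ["animal_id", "group", "region"]
    agg = counts.groupby(keys, as_index=False, sort=False)[_COUNT_FIELDS].sum()
    return agg


def load_counts(
    path,
    metadata_path=None,
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a counts CSV and its region metadata.

    Parameters
    ----------
    path
        CSV with header ``animal_id,group,region,n_dapi,n_td,n_cfos,n_double``.
        An optional ``sex`` column is accepted and ignored.
    metadata_path
        CSV with header ``region,anatomical_group``. When omitted, the default
        15-region panel is used.
    strict
        If True, duplicate (animal, region) rows raise instead of being summed.

    Returns
    -------
    (counts, metadata) : validated DataFrames, one count row per animal x region.
    """
    counts = pd.read_csv(path)
    metadata = pd.read_csv(metadata_path) if metadata_path is not None else default_region_metadata()
    _require_columns(counts, COUNT_COLUMNS, "counts table")
    _require_columns(metadata, METADATA_COLUMNS, "region metadata")

    dup = counts.duplicated(subset=["animal_id", "region"], keep=False)
    if dup.any():
        if strict:
            row = counts.index[dup][0]
            raise ValidationError(
                f"row {row}: duplicate (animal_id, region) = "
                f"({counts.loc[row, 'animal_id']!r}, {counts.loc[row, 'region']!r})"
            )
        warnings.warn(
            f"{int(dup.sum())} per-image rows detected; summing to one row per animal x region",
            stacklevel=2,
        )
        counts = aggregate_per_image(counts)

    counts = validate_counts(counts, metadata)

    groups_used = metadata.loc[
        metadata["region"].isin(counts["region"]), "anatomical_group"
    ]
    if groups_used.nunique() == 0:
        raise ValidationError("no region in the counts table maps to an anatomical group")
    return counts[COUNT_COLUMNS], metadata[METADATA_COLUMNS]


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write counts back to CSV in the canonical column order."""
    counts[COUNT_COLUMNS].to_csv(path, index=False)


BEHAVIOR_COLUMNS = ["animal_id", "freezing_threat_s", "freezing_neutral_s"]


def load_behavior(path, session_length_s: float | None = None) -> pd.DataFrame:
    """Load a behavior CSV (freezing seconds per context / light period)."""
    beh = pd.read_csv(path)
    _require_columns(beh, BEHAVIOR_COLUMNS, "behavior table")
    cols = BEHAVIOR_COLUMNS + [c for c in ("freezing_on_s", "freezing_off_s") if c in beh.columns]
    for col in cols[1:]:
        if (beh[col] < 0).any():
            row = beh.index[beh[col] < 0][0]
            raise ValidationError(f"row {row}: field {col} is negative")
        if session_length_s is not None and (beh[col] > session_length_s).any():
            row = beh.index[beh[col] > session_length_s][0]
            raise ValidationError(f"row {row}: field {col} exceeds session length")
    return beh[cols]


def discrimination_index(freezing_threat_s, freezing_neutral_s):
    """Context discrimination: (threat - neutral) / (threat + neutral), in [-1, 1].

    Contrasts freezing in the threatening vs a neutral context; +1 means all
    freezing was context-specific, 0 no discrimination. Undefined (raises)
    when both inputs are zero. Accepts scalars or aligned arrays.
    """
    threat = np.asarray(freezing_threat_s, dtype=float)
    neutral = np.asarray(freezing_neutral_s, dtype=float)
    if (threat < 0).any() or (neutral < 0).any():
        raise ValidationError("freezing times must be non-negative")
    total = threat + neutral
    if (total == 0).any():
        raise UndefinedResultError(
            "discrimination index undefined: freezing is zero in both contexts"
        )
    out = (threat - neutral) / total
    return float(out) if out.ndim == 0 else out


def freezing_on_off_difference(freezing_on_s, freezing_off_s):
    """Signed freezing difference between light ON and light OFF periods (seconds)."""
    on = np.asarray(freezing_on_s, dtype=float)
    off = np.asarray(freezing_off_s, dtype=float)
    if (on < 0).any() or (off < 0).any():
        raise ValidationError("freezing times must be non-negative")
    out = on - off
    return float(out) if out.ndim == 0 else out
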