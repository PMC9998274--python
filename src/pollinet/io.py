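"""Reading, validation and writing of the pipeline's tabular formats.

Two input tables drive everything downstream:

* **survey records** — one row per pollinator-visitation observation (or
  flowering-plant-only observation, ``visit_count == 0``) on one transect in
  one survey round;
* **island attributes** — one row per island with forest area (ha), distance
  to the mainland (m) and the number of paired edge/interior transects.

Interaction matrices (plants x pollinators) round-trip through plain CSV with
plant names in the first column.  All files are UTF-8, comma-separated, with
'.' as the decimal mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "site_id",
    "transect_id",
    "site_class",
    "is_mainland",
    "survey_round",
    "plant_species",
    "pollinator_species",
    "visit_count",
    "floral_area",
]

ATTRIBUTE_COLUMNS = ["site_id", "area_ha", "distance_to_mainland_m", "n_transect_pairs"]

SITE_CLASSES = ("edge", "interior")


class SchemaError(ValueError):
    """A required column is missing or has the wrong layout."""


class ValidationError(ValueError):
    """A row violates a field invariant (negative count, bad class, ...)."""


@dataclass(frozen=True)
class IslandAttributes:
    """Static attributes of one island (or mainland site)."""

    site_id: str
    area_ha: float
    distance_to_mainland_m: float
    n_transect_pairs: int


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _parse_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValidationError(f"cannot interpret is_mainland value {bad!r} as boolean")
    return out.astype(bool)


def read_survey_records(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a survey-record CSV.

    Parameters
    ----------
    path
        CSV file with the canonical header (see :data:`SURVEY_COLUMNS`).
    strict
        If True (default), any invalid row raises :class:`ValidationError`
        naming the offending row; if False, invalid rows are dropped with a
        logged warning.

    Returns
    -------
    pandas.DataFrame
        Validated records in file order, species names whitespace-normalised.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "transect_id": str,
                                  "plant_species": str, "pollinator_species": str})
    _require_columns(df, SURVEY_COLUMNS, "survey record table")
    df = df[SURVEY_COLUMNS].copy()

    for col in ("site_id", "transect_id", "plant_species", "pollinator_species"):
        df[col] = df[col].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    df["site_class"] = df["site_class"].astype(str).str.strip().str.lower()
    df["is_mainland"] = _parse_bool(df["is_mainland"])
    df["survey_round"] = pd.to_numeric(df["survey_round"], errors="coerce")
    df["visit_count"] = pd.to_numeric(df["visit_count"], errors="coerce")
    df["floral_area"] = pd.to_numeric(df["floral_area"], errors="coerce")

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask & ~bad]:
            reasons[idx] = reason
        bad.loc[mask] = True

    flag(~df["site_class"].isin(SITE_CLASSES), "site_class not 'edge' or 'interior'")
    flag(df["survey_round"].isna() | (df["survey_round"] < 1)
         | (df["survey_round"] != df["survey_round"].round()), "survey_round must be an integer >= 1")
    flag(df["visit_count"].isna() | (df["visit_count"] < 0)
         | (df["visit_count"] != df["visit_count"].round()), "visit_count must be a non-negative integer")
    flag(df["floral_area"].isna() | (df["floral_area"] < 0), "floral_area must be non-negative")

    if bad.any():
        first = int(df.index[bad][0])
        if strict:
            # +2: header line plus 1-based numbering, matching what a user
            # sees in the raw file.
            raise ValidationError(
                f"invalid survey record at file row {first + 2}: {reasons[first]}"
            )
        logger.warning("dropping %d invalid survey record(s); first bad row %d (%s)",
                       int(bad.sum()), first + 2, reasons[first])
        df = df[~bad]

    df["survey_round"] = df["survey_round"].astype(int)
    df["visit_count"] = df["visit_count"].astype(int)
    return df.reset_index(drop=True)


def write_survey_records(records: pd.DataFrame, path) -> None:
    """Write records with the canonical column order; inverse of the reader."""
    records[SURVEY_COLUMNS].to_csv(path, index=False)


def read_island_attributes(path) -> dict[str, IslandAttributes]:
    """Read the island attribute table into a mapping keyed by site id.

    Duplicated ``site_id`` values, non-positive areas or distances, and
    transect-pair counts outside 1..16 are rejected.
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, ATTRIBUTE_COLUMNS, "island attribute table")
    df["site_id"] = df["site_id"].str.strip()
    dups = df["site_id"][df["site_id"].duplicated()]
    if len(dups):
        raise ValidationError(f"duplicated site_id in attribute table: {dups.iloc[0]!r}")
    out: dict[str, IslandAttributes] = {}
    for _, row in df.iterrows():
        area = float(row["area_ha"])
        dist = float(row["distance_to_mainland_m"])
        pairs = int(row["n_transect_pairs"])
        if area <= 0:
            raise ValidationError(f"area_ha must be > 0 for site {row['site_id']!r}")
        if dist <= 0:
            raise ValidationError(f"distance_to_mainland_m must be > 0 for site {row['site_id']!r}")
        if not 1 <= pairs <= 16:
            raise ValidationError(f"n_transect_pairs must be in [1, 16] for site {row['site_id']!r}")
        out[row["site_id"]] = IslandAttributes(row["site_id"], area, dist, pairs)
    return out


def write_island_attributes(attributes: dict[str, IslandAttributes], path) -> None:
    rows = [[a.site_id, a.area_ha, a.distance_to_mainland_m, a.n_transect_pairs]
            for a in attributes.values()]
    pd.DataFrame(rows, columns=ATTRIBUTE_COLUMNS).to_csv(path, index=False)


def write_matrix(network, path) -> None:
    """Write a bipartite network's weight matrix as CSV.

    Plant rows, pollinator columns, integer cell weights; the first column
    holds the plant name.  ``read_matrix`` is its exact inverse.
    """
    df = pd.DataFrame(np.asarray(network.weights, dtype=int),
                      index=list(network.plant_names),
                      columns=list(network.pollinator_names))
    df.to_csv(path, index_label="plant")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix CSV back into (weights, plant_names, pollinator_names)."""
    df = pd.read_csv(path, index_col=0)
    weights = df.to_numpy(dtype=int) if df.size else np.zeros(df.shape, dtype=int)
    return weights, [str(i) for i in df.index], [str(c) for c in df.columns]
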