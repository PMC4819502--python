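"""Domain types, validation and tidy CSV input/output.

All stages of the pipeline exchange tidy long-format tables (one
observation per row) held in :class:`pandas.DataFrame`:

``plant`` tables
    columns ``species, block, distance, n_pct, d15n`` — one grass shoot
    sample per row.  ``species`` is one of the three focal grasses
    (``LC`` *Leymus chinensis*, ``SG`` *Stipa grandis*, ``AS``
    *Achnatherum sibiricum*); ``distance`` is the transect distance class
    in cm or ``REF`` for reference samples taken far from any shrub.
``soil`` tables
    columns ``compartment, block, n_pct, d15n`` — ``compartment`` is
    ``RS`` (rhizosphere), ``NRS`` (non-rhizosphere), a transect distance
    class, or ``REF``.
``community`` tables
    columns ``block, position, species_name, functional_group, biomass,
    height, abundance`` — one species per (block, position) quadrat,
    position ``Within`` (under the shrub canopy) or ``Open``.

Validation severity is split: physically impossible values (nitrogen
concentration <= 0 or >= 10 % dry mass) are errors; merely implausible
ones (|delta15N| > 20 per mil) raise a warning and are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "SPECIES",
    "DISTANCES_CM",
    "REF",
    "COMPARTMENTS",
    "POSITIONS",
    "FUNCTIONAL_GROUPS",
    "TableValidationError",
    "ratio_to_delta",
    "parse_distance",
    "distance_sort_key",
    "read_plant_table",
    "read_soil_table",
    "read_community_table",
    "write_table",
    "validate_plant_table",
    "validate_soil_table",
    "validate_community_table",
]

logger = logging.getLogger(__name__)

#: Focal grass species codes.
SPECIES = ("LC", "SG", "AS")

#: Transect sampling distances from the shrub-canopy edge, in cm.
DISTANCES_CM = (0, 20, 50, 100, 150, 300, 500)

#: Symbolic distance class for reference samples (>= 15 m from any shrub).
REF = "REF"

#: Soil compartments: rhizosphere, non-rhizosphere, transect distances, reference.
COMPARTMENTS = ("RS", "NRS") + tuple(str(d) for d in DISTANCES_CM) + (REF,)

POSITIONS = ("Within", "Open")
FUNCTIONAL_GROUPS = ("grass", "forb", "shrub")

PLANT_COLUMNS = ["species", "block", "distance", "n_pct", "d15n"]
SOIL_COLUMNS = ["compartment", "block", "n_pct", "d15n"]
COMMUNITY_COLUMNS = [
    "block",
    "position",
    "species_name",
    "functional_group",
    "biomass",
    "height",
    "abundance",
]

Distance = Union[int, str]


class TableValidationError(ValueError):
    """A table violates a schema invariant; ``errors`` lists offending rows."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "table validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


def ratio_to_delta(r_sample: float, r_standard: float) -> float:
    """Convert a molar 15N/14N ratio to delta15N in per mil.

    delta15N (per mil) = (R_sample / R_standard - 1) * 1000, with
    R_standard the 15N/14N ratio of atmospheric N2.

    Parameters
    ----------
    r_sample, r_standard : float
        Strictly positive molar isotope ratios.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError(
            f"isotope ratios must be positive, got r_sample={r_sample}, "
            f"r_standard={r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def parse_distance(value) -> Distance:
    """Parse a distance-class token: integer cm in the design, or ``"REF"``."""
    s = str(value).strip()
    if s.upper() == REF:
        return REF
    try:
        d = int(s)
    except ValueError:
        raise ValueError(f"unrecognised distance class {value!r}") from None
    if d not in DISTANCES_CM:
        raise ValueError(
            f"distance {d} cm is not one of the sampling distances {DISTANCES_CM}"
        )
    return d


def distance_sort_key(distance: Distance) -> float:
    """Sort key placing numeric distances in order and REF last."""
    return float("inf") if distance == REF else float(distance)


def sorted_distances(distances: Iterable[Distance]) -> list:
    return sorted(set(distances), key=distance_sort_key)


# ---------------------------------------------------------------------------
# validation


def _check_numeric_bounds(df: pd.DataFrame, errors: list) -> None:
    for i, row in df.iterrows():
        n = row["n_pct"]
        d = row["d15n"]
        if pd.isna(n) or pd.isna(d):
            errors.append(f"row {i}: missing n_pct or d15n")
            continue
        if not (0.0 < n < 10.0):
            errors.append(f"row {i}: n_pct={n} outside (0, 10) % dry mass")
        if abs(d) > 20.0:
            warnings.warn(
                f"row {i}: d15n={d} per mil outside the plausible [-20, 20] range",
                stacklevel=3,
            )


def validate_plant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a plant table in place and return it.

    Raises :class:`TableValidationError` naming every offending row.
    """
    errors: list = []
    missing = [c for c in PLANT_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {missing}"])
    for i, sp in df["species"].items():
        if sp not in SPECIES:
            errors.append(f"row {i}: unknown species code {sp!r}")
    parsed = []
    for i, val in df["distance"].items():
        try:
            parsed.append(parse_distance(val))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            parsed.append(None)
    df = df.copy()
    df["distance"] = parsed
    _check_numeric_bounds(df, errors)
    dup = df.duplicated(subset=["species", "block", "distance"], keep=False)
    for i in df.index[dup]:
        r = df.loc[i]
        errors.append(
            f"row {i}: duplicate key (species={r['species']}, block={r['block']}, "
            f"distance={r['distance']})"
        )
    if errors:
        raise TableValidationError(errors)
    df["block"] = df["block"].astype(int)
    return df


def validate_soil_table(df: pd.DataFrame) -> pd.DataFrame:
    errors: list = []
    missing = [c for c in SOIL_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {missing}"])
    comps = []
    for i, val in df["compartment"].items():
        s = str(val).strip()
        if s in COMPARTMENTS:
            comps.append(s)
        else:
            errors.append(f"row {i}: unknown compartment {val!r}")
            comps.append(None)
    df = df.copy()
    df["compartment"] = comps
    _check_numeric_bounds(df, errors)
    dup = df.duplicated(subset=["compartment", "block"], keep=False)
    for i in df.index[dup]:
        r = df.loc[i]
        errors.append(
            f"row {i}: duplicate key (compartment={r['compartment']}, "
            f"block={r['block']})"
        )
    if errors:
        raise TableValidationError(errors)
    df["block"] = df["block"].astype(int)
    return df


def validate_community_table(df: pd.DataFrame) -> pd.DataFrame:
    errors: list = []
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError([f"missing columns: {missing}"])
    df = df.copy()
    for i, row in df.iterrows():
        if row["position"] not in POSITIONS:
            errors.append(f"row {i}: position must be one of {POSITIONS}")
        if row["functional_group"] not in FUNCTIONAL_GROUPS:
            errors.append(f"row {i}: unknown functional group {row['functional_group']!r}")
        if pd.isna(row["biomass"]) or row["biomass"] < 0:
            errors.append(f"row {i}: biomass must be >= 0")
        # height/abundance may be missing (empty field), but not negative/zero height
        if not pd.isna(row["height"]) and row["height"] <= 0:
            errors.append(f"row {i}: height must be > 0 or missing")
        if not pd.isna(row["abundance"]) and row["abundance"] < 0:
            errors.append(f"row {i}: abundance must be >= 0 or missing")
    dup = df.duplicated(subset=["block", "position", "species_name"], keep=False)
    for i in df.index[dup]:
        r = df.loc[i]
        errors.append(
            f"row {i}: species {r['species_name']!r} listed twice for "
            f"(block={r['block']}, position={r['position']})"
        )
    if errors:
        raise TableValidationError(errors)
    df["block"] = df["block"].astype(int)
    return df


# ---------------------------------------------------------------------------
# readers / writer


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: object for c in columns})
    if df.empty:
        warnings.warn(f"{path}: file contains a header but no rows", stacklevel=3)
    return df


def read_plant_table(path) -> pd.DataFrame:
    """Read and validate a plant shoot-sample CSV."""
    df = _read_csv(path, PLANT_COLUMNS)
    for c in ("n_pct", "d15n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return validate_plant_table(df)


def read_soil_table(path) -> pd.DataFrame:
    """Read and validate a soil-sample CSV."""
    df = _read_csv(path, SOIL_COLUMNS)
    for c in ("n_pct", "d15n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return validate_soil_table(df)


def read_community_table(path) -> pd.DataFrame:
    """Read and validate a community-quadrat CSV (height/abundance may be empty)."""
    df = _read_csv(path, COMMUNITY_COLUMNS)
    for c in ("biomass", "height", "abundance"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return validate_community_table(df)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy table as UTF-8 CSV with full float precision.

    Missing height/abundance are written as empty fields (never 0).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
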