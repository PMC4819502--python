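"""Community responses to shrub encroachment.

Per-quadrat species evenness (Pielou's J on biomass proportions) and
paired Within-vs-Open contrasts across blocks for species-level biomass,
height and abundance and for functional-group biomass totals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import FUNCTIONAL_GROUPS, POSITIONS, validate_community_table

__all__ = [
    "EvennessResult",
    "PairedTestResult",
    "evenness",
    "evenness_by_quadrat",
    "paired_position_test",
    "functional_group_biomass",
    "evenness_position_test",
]

logger = logging.getLogger(__name__)


@dataclass
class EvennessResult:
    """Richness, Shannon diversity (nats) and Pielou evenness of one quadrat.

    ``evenness`` is H' / ln(S); it is undefined for a single-species
    quadrat (ln S = 0), flagged via ``defined = False``.
    """

    richness: int
    shannon: float
    evenness: float
    defined: bool


@dataclass
class PairedTestResult:
    """Paired t test of Within - Open differences across blocks."""

    target: str
    variable: str
    t: float
    df: int
    p_value: float
    mean_difference: float
    n_pairs: int
    n_dropped: int


def evenness(biomass, basis: str = "biomass") -> EvennessResult:
    """Pielou evenness of one quadrat from per-species biomass (or abundance).

    Zero values are dropped (they contribute nothing to the Shannon
    sum); all-zero input is an error.
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0) or np.any(~np.isfinite(b)):
        raise ValueError("biomass values must be finite and >= 0")
    b = b[b > 0]
    if b.size == 0:
        raise ValueError("all-zero biomass: evenness undefined")
    p = b / b.sum()
    h = float(-(p * np.log(p)).sum())
    s = int(b.size)
    if s == 1:
        return EvennessResult(richness=1, shannon=0.0, evenness=np.nan, defined=False)
    return EvennessResult(richness=s, shannon=h, evenness=h / np.log(s), defined=True)


def evenness_by_quadrat(records: pd.DataFrame, basis: str = "biomass") -> pd.DataFrame:
    """Evenness per (block, position) quadrat.

    ``basis`` selects the proportion base: ``"biomass"`` (default) or
    ``"abundance"``.
    """
    if basis not in ("biomass", "abundance"):
        raise ValueError("basis must be 'biomass' or 'abundance'")
    records = validate_community_table(records)
    rows = []
    for (blk, pos), g in records.groupby(["block", "position"], observed=True):
        vals = g[basis].dropna()
        res = evenness(vals.to_numpy())
        rows.append(
            {
                "block": blk,
                "position": pos,
                "richness": res.richness,
                "shannon": res.shannon,
                "evenness": res.evenness,
            }
        )
    return pd.DataFrame(rows)


def _paired_frame(records: pd.DataFrame, variable: str, mask) -> pd.DataFrame:
    sub = records[mask]
    agg = sub.groupby(["block", "position"], observed=True)[variable].sum(min_count=1)
    wide = agg.unstack("position")
    for p in POSITIONS:
        if p not in wide.columns:
            wide[p] = np.nan
    return wide[list(POSITIONS)]


def paired_position_test(
    records: pd.DataFrame,
    variable: str,
    species_name: Optional[str] = None,
    functional_group: Optional[str] = None,
) -> PairedTestResult:
    """Paired t test of the shrub effect (Within - Open) on one variable.

    Exactly one of ``species_name`` / ``functional_group`` selects the
    target; blocks missing either position are dropped and counted.  A
    zero-variance nonzero difference is reported with p below the
    smallest representable positive float rather than an error.
    """
    if (species_name is None) == (functional_group is None):
        raise ValueError("specify exactly one of species_name or functional_group")
    records = validate_community_table(records)
    if species_name is not None:
        mask = records["species_name"] == species_name
        target = species_name
        if not mask.any():
            raise ValueError(f"species {species_name!r} absent from the table")
    else:
        if functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"unknown functional group {functional_group!r}")
        mask = records["functional_group"] == functional_group
        target = functional_group
        if not mask.any():
            warnings.warn(f"no records for functional group {functional_group!r}")

    wide = _paired_frame(records, variable, mask)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("paired test %s/%s: dropped %d incomplete blocks", target, variable, n_dropped)
    if len(complete) < 2:
        raise ValueError(
            f"need >= 2 blocks with both positions for {target!r}, got {len(complete)}"
        )
    diff = (complete["Within"] - complete["Open"]).to_numpy(float)
    n = diff.size
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            t, p = 0.0, 1.0
        else:
            t = np.inf if mean_diff > 0 else -np.inf
            p = 5e-324  # smallest positive subnormal: certainty up to float resolution
    else:
        t, p = stats.ttest_rel(complete["Within"], complete["Open"])
        t, p = float(t), float(p)
    return PairedTestResult(
        target=target,
        variable=variable,
        t=t,
        df=n - 1,
        p_value=p,
        mean_difference=mean_diff,
        n_pairs=n,
        n_dropped=n_dropped,
    )


def functional_group_biomass(records: pd.DataFrame) -> pd.DataFrame:
    """Total biomass per block x position for each functional group.

    An empty group yields rows of 0 with a warning.
    """
    records = validate_community_table(records)
    frames = []
    index = records.groupby(["block", "position"], observed=True).size().index
    for grp in ("grass", "forb"):
        sub = records[records["functional_group"] == grp]
        if sub.empty:
            warnings.warn(f"no {grp} records; totals reported as 0")
            tot = pd.Series(0.0, index=index)
        else:
            tot = sub.groupby(["block", "position"], observed=True)["biomass"].sum()
            tot = tot.reindex(index, fill_value=0.0)
        frames.append(tot.rename(grp))
    out = pd.concat(frames, axis=1).reset_index()
    return out


def evenness_position_test(records: pd.DataFrame, basis: str = "biomass") -> PairedTestResult:
    """Paired Within-vs-Open contrast of per-block Pielou evenness."""
    ev = evenness_by_quadrat(records, basis=basis)
    wide = ev.pivot(index="block", columns="position", values="evenness")
    for p in POSITIONS:
        if p not in wide.columns:
            wide[p] = np.nan
    complete = wide[list(POSITIONS)].dropna()
    if len(complete) < 2:
        raise ValueError("need >= 2 blocks with evenness defined at both positions")
    diff = (complete["Within"] - complete["Open"]).to_numpy(float)
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if diff.mean() == 0 else np.sign(diff.mean()) * np.inf
        p = 1.0 if diff.mean() == 0 else 5e-324
    else:
        t, p = stats.ttest_rel(complete["Within"], complete["Open"])
        t, p = float(t), float(p)
    return PairedTestResult(
        target="evenness",
        variable=basis,
        t=t,
        df=len(complete) - 1,
        p_value=p,
        mean_difference=float(diff.mean()),
        n_pairs=len(complete),
        n_dropped=int(len(wide) - len(complete)),
    )
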