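"""Two-source delta15N mixing model for rhizodeposition-derived nitrogen.

The method quantifies what fraction of a grass's shoot nitrogen was
derived from the rhizodeposition (root exudates and fine-root turnover)
of a neighbouring N2-fixing shrub, using natural-abundance delta15N only:

1. The nitrogen enrichment of rhizosphere soil over non-rhizosphere soil
   is attributed entirely to rhizodeposition, giving the deposition
   fraction of rhizosphere-soil N::

       P_depo = (N_RS - N_NRS) / N_RS

2. The same fraction written as a two-source isotope mixing model,
   solved for the (unmeasurable) delta15N of rhizodeposition::

       d15N_depo = (d15N_RS - d15N_NRS) * N_RS / (N_RS - N_NRS) + d15N_NRS

3. With d15N_depo in hand, a second two-source mixing model partitions a
   grass shoot's N between rhizodeposition and reference soil N::

       P_transfer = (d15N_mix - d15N_ref) / (d15N_depo - d15N_ref)

   where d15N_mix is the shoot signature near the shrub and d15N_ref the
   species-specific signature of reference plants growing far from any
   shrub.

Uncertainty is propagated by a nonparametric block bootstrap: shrub
clusters (the design's replicate unit) are resampled with replacement,
and the whole chain is recomputed per draw.  Bootstrap draws for which
the end-members degenerate (N_RS <= N_NRS) are dropped and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import REF, SPECIES, distance_sort_key, validate_plant_table, validate_soil_table

__all__ = [
    "CLIPPED_LOW",
    "CLIPPED_HIGH",
    "DEGENERATE_END_MEMBERS",
    "DegenerateEndMembersError",
    "EndMembers",
    "prop_depo_concentration",
    "delta_depo",
    "prop_depo_isotope",
    "prop_transfer",
    "EndMemberEstimator",
    "TransferProfileEstimator",
    "estimate_end_members",
    "estimate_transfer_profile",
]

logger = logging.getLogger(__name__)

CLIPPED_LOW = "CLIPPED_LOW"
CLIPPED_HIGH = "CLIPPED_HIGH"
DEGENERATE_END_MEMBERS = "DEGENERATE_END_MEMBERS"


class DegenerateEndMembersError(ValueError):
    """The two sources are isotopically or chemically indistinguishable."""


@dataclass
class EndMembers:
    """Mixing-model end-members estimated from rhizosphere/non-rhizosphere soil.

    Attributes
    ----------
    n_rs, n_nrs : float
        Mean rhizosphere / non-rhizosphere soil N (% dry mass).
    d_rs, d_nrs : float
        Mean rhizosphere / non-rhizosphere soil delta15N (per mil).
    d_depo : float
        Derived delta15N of rhizodeposition (per mil).
    p_depo_soil : float
        Fraction of rhizosphere-soil N attributed to rhizodeposition.
    n_blocks : int
        Number of complete blocks (paired RS/NRS) used.
    boot_d_depo : ndarray
        Per-draw d_depo; NaN where the draw degenerated (n_rs <= n_nrs).
    boot_indices : ndarray of shape (n_boot, n_blocks)
        Resampled block positions per draw, shared with the plant stage so
        soil and plants are resampled jointly.
    """

    n_rs: float
    n_nrs: float
    d_rs: float
    d_nrs: float
    d_depo: float
    p_depo_soil: float
    n_blocks: int
    boot_d_depo: np.ndarray = field(default_factory=lambda: np.empty(0))
    boot_indices: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=int))
    n_degenerate_draws: int = 0

    def to_dict(self) -> dict:
        lo, hi = self.d_depo_interval()
        return {
            "n_rs": self.n_rs,
            "n_nrs": self.n_nrs,
            "d_rs": self.d_rs,
            "d_nrs": self.d_nrs,
            "d_depo": self.d_depo,
            "p_depo_soil": self.p_depo_soil,
            "n_blocks": self.n_blocks,
            "d_depo_ci_low": lo,
            "d_depo_ci_high": hi,
            "n_bootstrap_draws": int(self.boot_d_depo.size),
            "n_degenerate_draws": self.n_degenerate_draws,
        }

    def d_depo_interval(self, level: float = 0.95) -> tuple:
        """Percentile bootstrap interval for d_depo over non-degenerate draws."""
        kept = self.boot_d_depo[~np.isnan(self.boot_d_depo)]
        if kept.size == 0:
            return (self.d_depo, self.d_depo)
        a = 100 * (1 - level) / 2
        return (float(np.percentile(kept, a)), float(np.percentile(kept, 100 - a)))


# ---------------------------------------------------------------------------
# elementary mixing operations


def prop_depo_concentration(n_rs: float, n_nrs: float):
    """Deposition fraction of rhizosphere-soil N from the concentration contrast.

    Returns ``(n_rs - n_nrs) / n_rs``.  A value <= 0 (no rhizosphere
    enrichment) signals degenerate end-members; the fraction is still
    returned so callers can diagnose it, alongside a flag.

    Returns
    -------
    (fraction, degenerate) : tuple of (float, bool)
    """
    n_rs = np.asarray(n_rs, dtype=float)
    n_nrs = np.asarray(n_nrs, dtype=float)
    if np.any(n_rs <= 0) or np.any(n_nrs <= 0):
        raise ValueError("soil N concentrations must be positive")
    frac = (n_rs - n_nrs) / n_rs
    degenerate = frac <= 0
    if frac.ndim == 0:
        return float(frac), bool(degenerate)
    return frac, degenerate


def delta_depo(d_rs: float, d_nrs: float, n_rs: float, n_nrs: float):
    """delta15N of rhizodeposition from the RS/NRS isotopic and N contrasts.

    Returns ``(d_rs - d_nrs) * n_rs / (n_rs - n_nrs) + d_nrs``; requires
    a strict rhizosphere N enrichment (n_rs > n_nrs > 0).
    """
    n_rs = np.asarray(n_rs, dtype=float)
    n_nrs = np.asarray(n_nrs, dtype=float)
    if np.any(n_nrs <= 0):
        raise ValueError("soil N concentrations must be positive")
    if np.any(n_rs <= n_nrs):
        raise DegenerateEndMembersError(
            "rhizosphere soil N must exceed non-rhizosphere soil N "
            f"(got n_rs={n_rs}, n_nrs={n_nrs})"
        )
    out = (np.asarray(d_rs, float) - np.asarray(d_nrs, float)) * n_rs / (n_rs - n_nrs) + d_nrs
    return float(out) if out.ndim == 0 else out


def prop_depo_isotope(d_rs: float, d_nrs: float, d_depo: float):
    """Deposition fraction of rhizosphere-soil N from the two-source mixing model.

    Returns ``(d_rs - d_nrs) / (d_depo - d_nrs)``.
    """
    d_depo = np.asarray(d_depo, dtype=float)
    d_nrs = np.asarray(d_nrs, dtype=float)
    if np.any(d_depo == d_nrs):
        raise DegenerateEndMembersError(
            "d_depo equals d_nrs: deposition is isotopically indistinguishable "
            "from background soil"
        )
    out = (np.asarray(d_rs, float) - d_nrs) / (d_depo - d_nrs)
    return float(out) if out.ndim == 0 else out


def prop_transfer(d_mix: float, d_ref: float, d_depo: float):
    """Fraction of a grass shoot's N derived from shrub rhizodeposition.

    Two-source mixing between the rhizodeposition end-member (``d_depo``)
    and the species' reference signature (``d_ref``):
    ``raw = (d_mix - d_ref) / (d_depo - d_ref)``.

    Returns
    -------
    (raw, clipped, flags) : tuple
        ``raw`` may fall outside [0, 1] with noisy data; ``clipped`` is
        raw restricted to [0, 1]; ``flags`` records the clipping
        direction (``CLIPPED_LOW`` / ``CLIPPED_HIGH``).
    """
    if d_depo == d_ref:
        raise DegenerateEndMembersError(
            "d_depo equals d_ref: the two N sources are isotopically "
            "indistinguishable for this species"
        )
    raw = (d_mix - d_ref) / (d_depo - d_ref)
    clipped = min(1.0, max(0.0, raw))
    flags = set()
    if raw < 0.0:
        flags.add(CLIPPED_LOW)
    elif raw > 1.0:
        flags.add(CLIPPED_HIGH)
    return raw, clipped, flags


# ---------------------------------------------------------------------------
# estimators


def _block_compartment_matrix(soil: pd.DataFrame):
    """Per-block RS/NRS values for blocks where both compartments are present."""
    sub = soil[soil["compartment"].isin(["RS", "NRS"])]
    wide_n = sub.pivot(index="block", columns="compartment", values="n_pct")
    wide_d = sub.pivot(index="block", columns="compartment", values="d15n")
    for w in (wide_n, wide_d):
        for c in ("RS", "NRS"):
            if c not in w.columns:
                w[c] = np.nan
    complete = wide_n[["RS", "NRS"]].notna().all(axis=1) & wide_d[["RS", "NRS"]].notna().all(axis=1)
    blocks = wide_n.index[complete]
    return (
        np.asarray(blocks),
        wide_n.loc[blocks, "RS"].to_numpy(float),
        wide_n.loc[blocks, "NRS"].to_numpy(float),
        wide_d.loc[blocks, "RS"].to_numpy(float),
        wide_d.loc[blocks, "NRS"].to_numpy(float),
    )


class EndMemberEstimator(BaseEstimator):
    """Estimate the rhizodeposition end-member from paired RS/NRS soil samples.

    Point estimates are the block means of each compartment; the derived
    rhizodeposition delta15N is computed from those means.  Uncertainty
    comes from resampling blocks (shrub clusters) with replacement,
    keeping the RS/NRS pairing within each block, and recomputing the
    chain per draw.  Draws with n_rs <= n_nrs are undefined under the
    model and are dropped with a logged count.

    Parameters
    ----------
    n_boot : int
        Number of bootstrap draws.
    random_state : int or numpy Generator, optional
        Seed for the block resampling.

    Attributes
    ----------
    end_members_ : EndMembers
        Full result record, including bootstrap draws.
    d_depo_, p_depo_soil_, n_rs_, n_nrs_, d_rs_, d_nrs_ : float
        Convenience scalar views of the point estimates.
    n_blocks_ : int
    n_degenerate_draws_ : int
    """

    def __init__(self, n_boot: int = 1000, random_state=None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, soil: pd.DataFrame, y=None):
        soil = validate_soil_table(soil)
        blocks, n_rs, n_nrs, d_rs, d_nrs = _block_compartment_matrix(soil)
        if len(blocks) < 2:
            raise ValueError(
                "need >= 2 blocks with both RS and NRS observations, "
                f"got {len(blocks)}"
            )
        m_n_rs, m_n_nrs = float(n_rs.mean()), float(n_nrs.mean())
        m_d_rs, m_d_nrs = float(d_rs.mean()), float(d_nrs.mean())
        p_depo, degenerate = prop_depo_concentration(m_n_rs, m_n_nrs)
        if degenerate:
            raise DegenerateEndMembersError(
                "mean rhizosphere soil N does not exceed non-rhizosphere soil N; "
                "the deposition end-member cannot be derived"
            )
        d_dep = delta_depo(m_d_rs, m_d_nrs, m_n_rs, m_n_nrs)

        rng = np.random.default_rng(self.random_state)
        B = len(blocks)
        idx = rng.integers(0, B, size=(self.n_boot, B))
        bn_rs = n_rs[idx].mean(axis=1)
        bn_nrs = n_nrs[idx].mean(axis=1)
        bd_rs = d_rs[idx].mean(axis=1)
        bd_nrs = d_nrs[idx].mean(axis=1)
        ok = bn_rs > bn_nrs
        boot = np.full(self.n_boot, np.nan)
        boot[ok] = (bd_rs[ok] - bd_nrs[ok]) * bn_rs[ok] / (bn_rs[ok] - bn_nrs[ok]) + bd_nrs[ok]
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info(
                "end-member bootstrap: dropped %d/%d degenerate draws (n_rs <= n_nrs)",
                n_bad,
                self.n_boot,
            )

        self.end_members_ = EndMembers(
            n_rs=m_n_rs,
            n_nrs=m_n_nrs,
            d_rs=m_d_rs,
            d_nrs=m_d_nrs,
            d_depo=d_dep,
            p_depo_soil=p_depo,
            n_blocks=B,
            boot_d_depo=boot,
            boot_indices=idx,
            n_degenerate_draws=n_bad,
        )
        self.blocks_ = blocks
        self.n_rs_, self.n_nrs_ = m_n_rs, m_n_nrs
        self.d_rs_, self.d_nrs_ = m_d_rs, m_d_nrs
        self.d_depo_ = d_dep
        self.p_depo_soil_ = p_depo
        self.n_blocks_ = B
        self.n_degenerate_draws_ = n_bad
        return self


class TransferProfileEstimator(BaseEstimator):
    """Per species x distance transfer fractions with block-bootstrap intervals.

    For every (species, distance != REF) cell the point estimate applies
    the mixing model to the cell's mean shoot delta15N, the species'
    mean reference delta15N and the fitted deposition end-member.
    Intervals resample blocks jointly with the end-member bootstrap:
    draw *b* reuses the soil stage's resampled block set for the plant
    table, so shared block effects cancel coherently.

    Parameters
    ----------
    end_members : EndMembers or fitted EndMemberEstimator
    ci : float
        Bootstrap percentile interval level (default 0.95).
    per_block : bool
        If True, average per-block mixing ratios instead of mixing the
        per-cell means (exposed as an alternative; default False).

    Attributes
    ----------
    estimates_ : DataFrame
        Columns ``species, distance, p_transfer, p_transfer_raw, ci_low,
        ci_high, n_used, flags``.
    skipped_cells_ : list of (species, distance)
        Cells with no observations.
    """

    def __init__(self, end_members=None, ci: float = 0.95, per_block: bool = False):
        self.end_members = end_members
        self.ci = ci
        self.per_block = per_block

    def _resolve_end_members(self) -> EndMembers:
        em = self.end_members
        if isinstance(em, EndMemberEstimator):
            check_is_fitted(em)
            return em.end_members_
        if isinstance(em, EndMembers):
            return em
        raise TypeError("end_members must be an EndMembers or a fitted EndMemberEstimator")

    def fit(self, plants: pd.DataFrame, y=None):
        plants = validate_plant_table(plants)
        em = self._resolve_end_members()
        idx = em.boot_indices
        n_boot, B = idx.shape if idx.size else (0, em.n_blocks)

        species_present = [s for s in SPECIES if (plants["species"] == s).any()]
        no_ref = [
            s
            for s in species_present
            if ((plants["species"] == s) & (plants["distance"] == REF)).sum() < 2
        ]
        if no_ref:
            raise ValueError(
                "species without >= 2 reference (REF) observations: "
                + ", ".join(no_ref)
            )

        # block axis shared with the soil stage: positions map onto the same
        # resampled indices, matching soil blocks by label where possible
        blocks = np.asarray(sorted(plants["block"].unique()))
        if len(blocks) != B:
            # fall back to an independent plant-block resampling grid
            rng = np.random.default_rng(0 if idx.size == 0 else int(idx[0, 0]) + 1)
            idx = rng.integers(0, len(blocks), size=(max(n_boot, 1), len(blocks)))
            B = len(blocks)
        block_pos = {b: i for i, b in enumerate(blocks)}

        distances = sorted(
            (d for d in plants["distance"].unique() if d != REF), key=distance_sort_key
        )

        def cell_values(sub: pd.DataFrame) -> np.ndarray:
            v = np.full(B, np.nan)
            for _, r in sub.iterrows():
                v[block_pos[r["block"]]] = r["d15n"]
            return v

        rows = []
        skipped = []
        for sp in species_present:
            sp_df = plants[plants["species"] == sp]
            ref_vals = cell_values(sp_df[sp_df["distance"] == REF])
            d_ref = float(np.nanmean(ref_vals))
            if em.d_depo == d_ref:
                raise DegenerateEndMembersError(
                    f"d_depo equals the reference signature for species {sp}"
                )
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                boot_ref = np.nanmean(ref_vals[idx], axis=1) if idx.size else np.empty(0)
            for dist in distances:
                sub = sp_df[sp_df["distance"] == dist]
                if sub.empty:
                    skipped.append((sp, dist))
                    logger.warning("no observations for %s at %s cm; cell skipped", sp, dist)
                    continue
                mix_vals = cell_values(sub)
                if self.per_block:
                    # per-block mixing ratios averaged, instead of the mixing
                    # model applied to cell means
                    both = ~np.isnan(mix_vals) & ~np.isnan(ref_vals)
                    if not both.any():
                        skipped.append((sp, dist))
                        continue
                    ratios = [
                        prop_transfer(m, r, em.d_depo)[0]
                        for m, r in zip(mix_vals[both], ref_vals[both])
                    ]
                    raw = float(np.mean(ratios))
                    clipped = min(1.0, max(0.0, raw))
                    flags = set()
                    if raw < 0:
                        flags.add(CLIPPED_LOW)
                    elif raw > 1:
                        flags.add(CLIPPED_HIGH)
                else:
                    d_mix = float(np.nanmean(mix_vals))
                    raw, clipped, flags = prop_transfer(d_mix, d_ref, em.d_depo)
                if em.p_depo_soil <= 0:
                    flags.add(DEGENERATE_END_MEMBERS)
                ci_low = ci_high = np.nan
                if idx.size:
                    # a draw that resamples only blocks missing at this cell
                    # yields NaN and is excluded below
                    with np.errstate(invalid="ignore"), warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        boot_mix = np.nanmean(mix_vals[idx], axis=1)
                    denom = em.boot_d_depo - boot_ref
                    with np.errstate(invalid="ignore", divide="ignore"):
                        draws = (boot_mix - boot_ref) / denom
                    draws = draws[np.isfinite(draws)]
                    if draws.size:
                        a = 100 * (1 - self.ci) / 2
                        ci_low = float(np.percentile(draws, a))
                        ci_high = float(np.percentile(draws, 100 - a))
                rows.append(
                    {
                        "species": sp,
                        "distance": dist,
                        "p_transfer": clipped,
                        "p_transfer_raw": raw,
                        "ci_low": ci_low,
                        "ci_high": ci_high,
                        "n_used": int(len(sub)),
                        "flags": ";".join(sorted(flags)),
                    }
                )
                if flags:
                    logger.info("cell (%s, %s): flags %s", sp, dist, sorted(flags))

        self.estimates_ = pd.DataFrame(
            rows,
            columns=[
                "species",
                "distance",
                "p_transfer",
                "p_transfer_raw",
                "ci_low",
                "ci_high",
                "n_used",
                "flags",
            ],
        )
        self.skipped_cells_ = skipped
        self.end_members_resolved_ = em
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers


def estimate_end_members(
    soil: pd.DataFrame, rng_seed=None, n_boot: int = 1000
) -> EndMembers:
    """Functional wrapper around :class:`EndMemberEstimator`."""
    return EndMemberEstimator(n_boot=n_boot, random_state=rng_seed).fit(soil).end_members_


def estimate_transfer_profile(
    plants: pd.DataFrame,
    end_members: EndMembers,
    rng_seed=None,
    n_boot: Optional[int] = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Functional wrapper around :class:`TransferProfileEstimator`.

    ``rng_seed``/``n_boot`` only matter when ``end_members`` carries no
    bootstrap draws of its own (the draws define the joint resampling).
    """
    if end_members.boot_indices.size == 0 and n_boot:
        rng = np.random.default_rng(rng_seed)
        B = end_members.n_blocks
        end_members.boot_indices = rng.integers(0, B, size=(n_boot, B))
        end_members.boot_d_depo = np.full(n_boot, end_members.d_depo)
    est = TransferProfileEstimator(end_members=end_members, ci=ci).fit(plants)
    return est.estimates_
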