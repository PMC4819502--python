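"""Forward simulation of the blocked shrub-transect field study.

The generator produces, from known truth, the three tables the pipeline
consumes: soil samples (rhizosphere/non-rhizosphere pairs under the
shrub, plus a flat transect), grass shoot samples along blocked
transects radiating from six shrub clusters, and paired Within/Open
community quadrats.  Because every cell's true transfer fraction is
recorded, the full estimation chain can be tested for exact recovery
(zero noise) and for calibration (noisy replicates).

Design defaults mirror the emulated study: 6 shrub-cluster blocks,
transect distances 0, 20, 50, 100, 150, 300, 500 cm plus a reference
position, three grass species with contrasting transfer profiles
(rhizomatous grass: constant fraction with distance; bunchgrass:
transfer only at the canopy edge; endophyte-infected bunchgrass: none),
and the stated missing cells (5 replicates for LC at 0 cm, 4 at 500 cm;
5 for AS at 0 cm, 4 at 20 cm).

Shoot delta15N at a cell with true transfer fraction P is the exact
mixture ``P * d_depo_true + (1 - P) * d_ref_mean`` plus a block random
intercept and residual Gaussian noise; shoot N follows
``n_ref_mean * (1 + n_gain * P)``.  Soil truth is specified through the
deposition fraction and signature, from which the implied rhizosphere
means follow by inverting the mixing relations, so the generated truth
satisfies the estimator's identities by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import DISTANCES_CM, REF, SPECIES

__all__ = [
    "SpeciesProfile",
    "SoilTruth",
    "FieldDesign",
    "CommunityEffect",
    "CommunitySpecies",
    "true_fraction",
    "generate",
    "generate_community",
    "default_profiles",
    "default_soil_truth",
    "default_design",
    "default_community_pool",
    "default_community_effects",
]

logger = logging.getLogger(__name__)

TRANSFER_SHAPES = ("constant", "step_at_zero", "exponential_decay", "none")

#: floor applied to noisy N-concentration draws (% dry mass)
N_PCT_FLOOR = 1e-3


@dataclass
class SpeciesProfile:
    """True transfer behaviour and reference distributions for one grass.

    ``n_gain`` couples shoot N to the transfer fraction: the mean N
    concentration at a cell is ``n_ref_mean * (1 + n_gain * P)``.
    """

    species: str
    transfer_shape: str
    p0: float
    decay_length: Optional[float] = None
    d_ref_mean: float = 4.0
    d_ref_sd: float = 0.3
    n_ref_mean: float = 1.5
    n_ref_sd: float = 0.08
    n_gain: float = 0.5

    def __post_init__(self):
        if self.transfer_shape not in TRANSFER_SHAPES:
            raise ValueError(f"unknown transfer_shape {self.transfer_shape!r}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.transfer_shape == "exponential_decay" and not (
            self.decay_length and self.decay_length > 0
        ):
            raise ValueError("exponential_decay requires decay_length > 0")
        if self.d_ref_sd < 0 or self.n_ref_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SoilTruth:
    """True soil end-member state, parameterised by the deposition pool.

    The rhizosphere means are implied:
    ``n_rs = n_nrs / (1 - p_depo_soil)`` and
    ``d_rs = p_depo * d_depo + (1 - p_depo) * d_nrs``, so the generated
    truth inverts exactly through the estimation chain.
    """

    d_nrs_true: float = 3.0
    n_nrs_true: float = 0.15
    d_depo_true: float = -3.0
    p_depo_soil_true: float = 0.25
    soil_noise_sd_delta: float = 0.2
    soil_noise_sd_n: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.p_depo_soil_true < 1.0:
            raise ValueError("p_depo_soil_true must lie in (0, 1)")
        if self.n_nrs_true <= 0:
            raise ValueError("n_nrs_true must be positive")

    @property
    def n_rs_true(self) -> float:
        return self.n_nrs_true / (1.0 - self.p_depo_soil_true)

    @property
    def d_rs_true(self) -> float:
        p = self.p_depo_soil_true
        return p * self.d_depo_true + (1.0 - p) * self.d_nrs_true


DEFAULT_MISSING_CELLS: Dict[Tuple[str, int], int] = {
    ("LC", 0): 5,
    ("LC", 500): 4,
    ("AS", 0): 5,
    ("AS", 20): 4,
}


@dataclass
class FieldDesign:
    """Sampling layout and noise structure of the blocked transect design."""

    n_blocks: int = 6
    distances: Sequence[int] = DISTANCES_CM
    missing_cells: Dict[Tuple[str, int], int] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_CELLS)
    )
    plant_noise_sd_delta: float = 0.3
    plant_noise_sd_n: float = 0.08
    block_sd_delta: float = 0.1
    block_sd_n: float = 0.03
    seed: Optional[int] = None

    def __post_init__(self):
        for (sp, dist), n in self.missing_cells.items():
            if n > self.n_blocks:
                raise ValueError(
                    f"missing_cells[{sp!r}, {dist}] = {n} exceeds n_blocks={self.n_blocks}"
                )
            if sp not in SPECIES or dist not in tuple(self.distances):
                raise ValueError(f"missing_cells key ({sp!r}, {dist}) not in the design")


def true_fraction(profile: SpeciesProfile, distance) -> float:
    """True transfer fraction of ``profile`` at a transect distance (cm)."""
    if distance == REF:
        raise ValueError("the reference position has no transfer fraction")
    d = float(distance)
    if profile.transfer_shape == "constant":
        return profile.p0
    if profile.transfer_shape == "step_at_zero":
        return profile.p0 if d == 0 else 0.0
    if profile.transfer_shape == "exponential_decay":
        return profile.p0 * float(np.exp(-d / profile.decay_length))
    return 0.0  # "none"


def default_profiles() -> List[SpeciesProfile]:
    """Profiles for the three focal grasses.

    LC (rhizomatous): constant high transfer fraction out to 500 cm with
    an enriched reference signature near 4 per mil; SG (bunchgrass):
    transfer only at the canopy edge; AS (endophyte-infected bunchgrass):
    no rhizodeposition uptake, higher shoot N.
    """
    return [
        SpeciesProfile("LC", "constant", 0.47, d_ref_mean=4.0, n_ref_mean=1.4, n_gain=0.6),
        SpeciesProfile("SG", "step_at_zero", 0.19, d_ref_mean=2.0, n_ref_mean=1.1, n_gain=0.5),
        SpeciesProfile("AS", "none", 0.0, d_ref_mean=1.0, n_ref_mean=1.8, n_gain=0.5),
    ]


def default_soil_truth() -> SoilTruth:
    return SoilTruth()


def default_design(seed: Optional[int] = None) -> FieldDesign:
    return FieldDesign(seed=seed)


def _rng(design_seed, override) -> np.random.Generator:
    if override is not None:
        return override if isinstance(override, np.random.Generator) else np.random.default_rng(override)
    return np.random.default_rng(design_seed)


def generate(
    design: FieldDesign,
    soil: SoilTruth,
    profiles: Sequence[SpeciesProfile],
    rng=None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one realisation of the field campaign.

    Returns
    -------
    (plant_table, soil_table, truth_table) : tuple of DataFrame
        Tables in the tidy interchange schema; ``truth_table`` records
        the true transfer fraction of every (species, distance) cell.
    """
    by_species = {p.species: p for p in profiles}
    missing = set(SPECIES) - set(by_species)
    if missing:
        raise ValueError(f"profiles missing for species: {sorted(missing)}")
    rng = _rng(design.seed, rng)
    blocks = np.arange(1, design.n_blocks + 1)

    # block random intercepts, shared by all plant samples within a block
    b_delta = rng.normal(0.0, design.block_sd_delta, design.n_blocks)
    b_n = rng.normal(0.0, design.block_sd_n, design.n_blocks)

    soil_rows = []
    for i, blk in enumerate(blocks):
        for comp, d_mean, n_mean in (
            ("RS", soil.d_rs_true, soil.n_rs_true),
            ("NRS", soil.d_nrs_true, soil.n_nrs_true),
        ):
            soil_rows.append(
                {
                    "compartment": comp,
                    "block": blk,
                    "n_pct": max(
                        N_PCT_FLOOR,
                        n_mean + rng.normal(0.0, soil.soil_noise_sd_n),
                    ),
                    "d15n": d_mean + rng.normal(0.0, soil.soil_noise_sd_delta),
                }
            )
        # transect + reference soil: flat at the non-rhizosphere means
        for comp in tuple(str(d) for d in design.distances) + (REF,):
            soil_rows.append(
                {
                    "compartment": comp,
                    "block": blk,
                    "n_pct": max(
                        N_PCT_FLOOR,
                        soil.n_nrs_true + rng.normal(0.0, soil.soil_noise_sd_n),
                    ),
                    "d15n": soil.d_nrs_true + rng.normal(0.0, soil.soil_noise_sd_delta),
                }
            )

    plant_rows = []
    truth_rows = []
    for sp in SPECIES:
        prof = by_species[sp]
        for dist in design.distances:
            p_true = true_fraction(prof, dist)
            truth_rows.append({"species": sp, "distance": dist, "p_true": p_true})
            d_mean = p_true * soil.d_depo_true + (1.0 - p_true) * prof.d_ref_mean
            n_mean = prof.n_ref_mean * (1.0 + prof.n_gain * p_true)
            n_reps = design.missing_cells.get((sp, dist), design.n_blocks)
            # drop the highest-numbered blocks to realise missing cells
            for i, blk in enumerate(blocks[:n_reps]):
                plant_rows.append(
                    {
                        "species": sp,
                        "block": blk,
                        "distance": dist,
                        "n_pct": max(
                            N_PCT_FLOOR,
                            n_mean + b_n[i] + rng.normal(0.0, design.plant_noise_sd_n),
                        ),
                        "d15n": d_mean
                        + b_delta[i]
                        + rng.normal(0.0, design.plant_noise_sd_delta),
                    }
                )
        for i, blk in enumerate(blocks):
            plant_rows.append(
                {
                    "species": sp,
                    "block": blk,
                    "distance": REF,
                    "n_pct": max(
                        N_PCT_FLOOR,
                        prof.n_ref_mean + b_n[i] + rng.normal(0.0, prof.n_ref_sd),
                    ),
                    "d15n": prof.d_ref_mean
                    + b_delta[i]
                    + rng.normal(0.0, prof.d_ref_sd),
                }
            )

    plant = pd.DataFrame(plant_rows)
    soil_df = pd.DataFrame(soil_rows)
    truth = pd.DataFrame(truth_rows)
    return plant, soil_df, truth


# ---------------------------------------------------------------------------
# community generator


@dataclass
class CommunitySpecies:
    """One member of the community species pool."""

    species_name: str
    functional_group: str
    biomass_mean: float
    biomass_sd: float = 0.0
    height_mean: Optional[float] = None
    height_sd: float = 0.0
    abundance_mean: Optional[float] = None
    abundance_sd: float = 0.0


@dataclass
class CommunityEffect:
    """Additive Within - Open mean shifts for one species."""

    species_name: str
    biomass_shift: float = 0.0
    height_shift: float = 0.0
    abundance_shift: float = 0.0


def default_community_pool() -> List[CommunitySpecies]:
    """Species pool for the semi-arid steppe community.

    The three focal grasses dominate biomass; a tail of forbs supplies
    the evenness-relevant background.
    """
    return [
        CommunitySpecies("Leymus chinensis", "grass", 90.0, 18.0, 45.0, 6.0, 110.0, 25.0),
        CommunitySpecies("Stipa grandis", "grass", 60.0, 14.0, 40.0, 6.0, 40.0, 12.0),
        CommunitySpecies("Achnatherum sibiricum", "grass", 45.0, 12.0, 50.0, 7.0, 30.0, 10.0),
        CommunitySpecies("Cleistogenes squarrosa", "grass", 12.0, 4.0),
        CommunitySpecies("Artemisia frigida", "forb", 10.0, 4.0),
        CommunitySpecies("Potentilla acaulis", "forb", 6.0, 2.5),
        CommunitySpecies("Allium ramosum", "forb", 5.0, 2.0),
        CommunitySpecies("Kochia prostrata", "forb", 4.0, 2.0),
        CommunitySpecies("Chenopodium glaucum", "forb", 3.0, 1.5),
    ]


FOCAL_NAMES = {
    "LC": "Leymus chinensis",
    "SG": "Stipa grandis",
    "AS": "Achnatherum sibiricum",
}


def default_community_effects() -> List[CommunityEffect]:
    """Within - Open shifts emulating the shrub's species-specific impact:

    the rhizomatous grass grows taller and heavier inside the canopy,
    both bunchgrasses lose biomass, and the endophyte-infected one also
    loses individuals — concentrating biomass and lowering evenness
    within the canopy.
    """
    return [
        CommunityEffect("Leymus chinensis", biomass_shift=35.0, height_shift=12.0),
        CommunityEffect("Stipa grandis", biomass_shift=-25.0, height_shift=-5.0),
        CommunityEffect(
            "Achnatherum sibiricum", biomass_shift=-20.0, abundance_shift=-12.0
        ),
        # forbs shaded out under the canopy
        CommunityEffect("Artemisia frigida", biomass_shift=-4.0),
        CommunityEffect("Potentilla acaulis", biomass_shift=-2.5),
        CommunityEffect("Allium ramosum", biomass_shift=-2.0),
        CommunityEffect("Kochia prostrata", biomass_shift=-1.5),
        CommunityEffect("Chenopodium glaucum", biomass_shift=-1.0),
        CommunityEffect("Cleistogenes squarrosa", biomass_shift=-5.0),
    ]


def generate_community(
    design: FieldDesign,
    effects: Optional[Sequence[CommunityEffect]] = None,
    pool: Optional[Sequence[CommunitySpecies]] = None,
    rng=None,
) -> pd.DataFrame:
    """Simulate paired Within/Open quadrats per block.

    Negative biomass/abundance draws are truncated at 0 with a logged
    count; missing height/abundance stays missing (only the focal
    grasses have height and abundance recorded).
    """
    pool = list(pool) if pool is not None else default_community_pool()
    effects = list(effects) if effects is not None else default_community_effects()
    eff_by_name = {e.species_name: e for e in effects}
    focal = set(FOCAL_NAMES.values())
    missing_focal = focal - {s.species_name for s in pool}
    if missing_focal:
        raise ValueError(f"community pool lacks the focal grasses: {sorted(missing_focal)}")
    rng = _rng(design.seed, rng)

    rows = []
    n_truncated = 0
    for blk in range(1, design.n_blocks + 1):
        for position in ("Within", "Open"):
            for spc in pool:
                eff = eff_by_name.get(spc.species_name, CommunityEffect(spc.species_name))
                within = position == "Within"
                biomass = spc.biomass_mean + (eff.biomass_shift if within else 0.0)
                biomass += rng.normal(0.0, spc.biomass_sd) if spc.biomass_sd else 0.0
                if biomass < 0:
                    biomass = 0.0
                    n_truncated += 1
                height = np.nan
                if spc.height_mean is not None:
                    height = spc.height_mean + (eff.height_shift if within else 0.0)
                    height += rng.normal(0.0, spc.height_sd) if spc.height_sd else 0.0
                    height = max(height, 1.0)
                abundance = np.nan
                if spc.abundance_mean is not None:
                    abundance = spc.abundance_mean + (
                        eff.abundance_shift if within else 0.0
                    )
                    abundance += (
                        rng.normal(0.0, spc.abundance_sd) if spc.abundance_sd else 0.0
                    )
                    if abundance < 0:
                        abundance = 0.0
                        n_truncated += 1
                rows.append(
                    {
                        "block": blk,
                        "position": position,
                        "species_name": spc.species_name,
                        "functional_group": spc.functional_group,
                        "biomass": biomass,
                        "height": height,
                        "abundance": abundance,
                    }
                )
    if n_truncated:
        logger.info("community generator: truncated %d negative draws at 0", n_truncated)
    return pd.DataFrame(rows)
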