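"""Run configuration: a single YAML file drives every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .simulate import (
    CommunityEffect,
    CommunitySpecies,
    FieldDesign,
    SoilTruth,
    SpeciesProfile,
    default_community_effects,
    default_community_pool,
    default_design,
    default_profiles,
    default_soil_truth,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a full run needs: seeding, paths, generator truth."""

    seed: int = 0
    n_boot: int = 1000
    alpha: float = 0.05
    out_dir: str = "outputs"
    paths: Dict[str, str] = field(default_factory=dict)
    design: FieldDesign = field(default_factory=default_design)
    soil_truth: SoilTruth = field(default_factory=default_soil_truth)
    profiles: List[SpeciesProfile] = field(default_factory=default_profiles)
    community_pool: List[CommunitySpecies] = field(default_factory=default_community_pool)
    community_effects: List[CommunityEffect] = field(default_factory=default_community_effects)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def table_path(self, name: str) -> Path:
        """Resolve a table path: explicit ``paths`` entry or out_dir default."""
        if name in self.paths:
            return Path(self.paths[name])
        return Path(self.out_dir) / f"{name}.csv"


def _parse_missing_cells(raw) -> Dict:
    out = {}
    for key, n in (raw or {}).items():
        if isinstance(key, str):
            sp, dist = key.split("@")
            out[(sp.strip(), int(dist))] = int(n)
        else:
            sp, dist = key
            out[(sp, int(dist))] = int(n)
    return out


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load a YAML config; keys absent from the file take package defaults.

    ``overrides`` (e.g. from CLI flags) take precedence over file keys.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", {}) or {}
    cfg = {k: v for k, v in raw.items() if k in ("seed", "n_boot", "alpha", "out_dir", "paths")}
    for k, v in overrides.items():
        if v is not None:
            cfg[k] = v

    design_kw = dict(gen.get("design") or {})
    if "missing_cells" in design_kw:
        design_kw["missing_cells"] = _parse_missing_cells(design_kw["missing_cells"])
    design = FieldDesign(**design_kw) if design_kw else default_design()
    if "seed" in cfg:
        design.seed = int(cfg["seed"])

    soil = SoilTruth(**(gen.get("soil_truth") or {})) if gen.get("soil_truth") else default_soil_truth()
    profiles = (
        [SpeciesProfile(**p) for p in gen["profiles"]]
        if gen.get("profiles")
        else default_profiles()
    )
    comm = gen.get("community") or {}
    pool = (
        [CommunitySpecies(**s) for s in comm["pool"]]
        if comm.get("pool")
        else default_community_pool()
    )
    effects = (
        [CommunityEffect(**e) for e in comm["effects"]]
        if comm.get("effects")
        else default_community_effects()
    )
    return RunConfig(
        design=design,
        soil_truth=soil,
        profiles=profiles,
        community_pool=pool,
        community_effects=effects,
        **cfg,
    )
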