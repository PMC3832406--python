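"""Run configuration and plain-text serialisation.

One YAML configuration drives a full pipeline run; every source of
randomness flows from its single ``master_seed``. Parameter sets
round-trip through a flat ``name = value`` text format, and site
archetypes round-trip through YAML, both bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ReefState, SiteParams
from .scenarios import BLEACHING_LEVELS, FISHING_LEVELS, WATER_QUALITY_LEVELS
from .sites import ARCHETYPE_LABELS, SiteArchetype

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_params",
    "read_params",
    "site_to_dict",
    "site_from_dict",
]

#: Defaults mirror the standard study design: 20 replicates, 40-year
#: horizon, snapshots at years 5/10/20/40, 4999 permutations.
_DEFAULTS = dict(
    n_replicates=20,
    horizon_years=40,
    snapshot_years=(5, 10, 20, 40),
    n_perm=4999,
    fishing_levels=tuple(FISHING_LEVELS),
    bleaching_levels=tuple(BLEACHING_LEVELS),
    water_levels=tuple(WATER_QUALITY_LEVELS),
    jitter=0.0,
    interaction_tolerance=0.0,
    output_dir="results",
    verbosity=1,
)


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end pipeline run."""

    sites: tuple[str, ...]
    master_seed: int
    n_replicates: int = _DEFAULTS["n_replicates"]
    horizon_years: int = _DEFAULTS["horizon_years"]
    snapshot_years: tuple[int, ...] = _DEFAULTS["snapshot_years"]
    n_perm: int = _DEFAULTS["n_perm"]
    fishing_levels: tuple[str, ...] = _DEFAULTS["fishing_levels"]
    bleaching_levels: tuple[str, ...] = _DEFAULTS["bleaching_levels"]
    water_levels: tuple[str, ...] = _DEFAULTS["water_levels"]
    jitter: float = _DEFAULTS["jitter"]
    interaction_tolerance: float = _DEFAULTS["interaction_tolerance"]
    output_dir: str = _DEFAULTS["output_dir"]
    verbosity: int = _DEFAULTS["verbosity"]
    site_file: str | None = None

    def validate(self) -> None:
        if not self.sites:
            raise ValueError("config must name at least one site")
        for s in self.sites:
            if s not in ARCHETYPE_LABELS:
                raise ValueError(
                    f"unknown site {s!r}; expected one of {ARCHETYPE_LABELS}"
                )
        for name in ("master_seed", "n_replicates", "horizon_years", "n_perm"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n_replicates < 1 or self.n_perm < 1:
            raise ValueError("n_replicates and n_perm must be >= 1")
        for y in self.snapshot_years:
            if not 0 <= y <= self.horizon_years:
                raise ValueError(
                    f"snapshot year {y} outside horizon 0..{self.horizon_years}"
                )
        for lvl in self.fishing_levels:
            if lvl not in FISHING_LEVELS:
                raise ValueError(f"unknown fishing level {lvl!r}")
        for lvl in self.bleaching_levels:
            if lvl not in BLEACHING_LEVELS:
                raise ValueError(f"unknown bleaching level {lvl!r}")
        for lvl in self.water_levels:
            if lvl not in WATER_QUALITY_LEVELS:
                raise ValueError(f"unknown water-quality level {lvl!r}")
        if not 0.0 <= self.jitter <= 0.5:
            raise ValueError("jitter must be in [0, 0.5]")
        if self.site_file is not None and not Path(self.site_file).exists():
            raise ValueError(f"site file {self.site_file!r} does not exist")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing optional keys receive the standard defaults; unknown keys are
    rejected so typos cannot silently change a run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")

    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    required = {"sites", "master_seed"}
    missing = required - set(raw)
    if missing:
        raise ValueError(f"missing required config key(s): {sorted(missing)}")

    for key in ("sites", "snapshot_years", "fishing_levels",
                "bleaching_levels", "water_levels"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if isinstance(raw["sites"], str):
        raw["sites"] = (raw["sites"],)
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# --------------------------------------------------------------------------
# flat parameter files


_PARAM_UNITS = {
    "coral_growth": "yr-1 per unit EAC",
    "coral_mortality": "yr-1",
    "coral_crowding": "yr-1 per unit coral",
    "coral_recruit_ext": "yr-1 per unit substrate",
    "coral_recruit_endo": "yr-1 per unit substrate per unit coral",
    "turf_emergence": "yr-1",
    "turf_senescence": "yr-1",
    "turf_to_macroalgae": "yr-1",
    "macroalgae_growth": "yr-1 per unit macroalgae",
    "macroalgae_senescence": "yr-1",
    "macroalgae_overgrowth": "yr-1 per unit macroalgae",
    "turf_overgrowth": "yr-1 per unit macroturf",
    "graze_herb_eac": "yr-1 per g m-2",
    "graze_herb_turf": "yr-1 per g m-2",
    "graze_herb_macroalgae": "yr-1 per g m-2",
    "graze_urchin_eac": "yr-1 per g m-2",
    "graze_urchin_turf": "yr-1 per g m-2",
    "graze_urchin_macroalgae": "yr-1 per g m-2",
    "algal_yield": "g m-2 per unit cover",
    "assim_herb": "dimensionless",
    "assim_pisc": "dimensionless",
    "herb_recruit": "g m-2 yr-1",
    "pisc_recruit": "g m-2 yr-1",
    "herb_mortality": "yr-1",
    "pisc_mortality": "yr-1",
    "piscivory": "yr-1 per g m-2",
    "urchin_growth": "yr-1",
    "urchin_capacity": "g m-2",
    "recruit_floor": "dimensionless",
    "recruit_saturation": "proportional cover",
}


def write_params(params: SiteParams, path: str | Path) -> None:
    """Write a parameter set as flat ``name = value`` lines with unit
    comments; booleans serialise as true/false."""
    lines = []
    for f in fields(params):
        value = getattr(params, f.name)
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        else:
            rendered = repr(float(value))
        unit = _PARAM_UNITS.get(f.name)
        comment = f"  # {unit}" if unit else ""
        lines.append(f"{f.name} = {rendered}{comment}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: str | Path) -> SiteParams:
    """Read a flat parameter file written by :func:`write_params`."""
    values: dict[str, object] = {}
    known = {f.name for f in fields(SiteParams)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'name = value'")
        name, _, raw = line.partition("=")
        name = name.strip()
        raw = raw.strip()
        if name not in known:
            raise ValueError(f"line {lineno}: unknown parameter {name!r}")
        if raw in ("true", "false"):
            values[name] = raw == "true"
        else:
            values[name] = float(raw)
    params = SiteParams(**values)
    params.validate()
    return params


# --------------------------------------------------------------------------
# site archetype round-trip


def site_to_dict(site: SiteArchetype) -> dict:
    return {
        "label": site.label,
        "urchins_present": bool(site.urchins_present),
        "area_note": site.area_note,
        "initial": {
            name: float(getattr(site.initial, name))
            for name in (
                "coral", "eac", "macroturf", "macroalgae",
                "herbivore_biomass", "piscivore_biomass", "urchin_biomass",
            )
        },
        "params": {
            f.name: (bool(v) if isinstance(v := getattr(site.params, f.name), bool)
                     else float(v))
            for f in fields(site.params)
        },
    }


def site_from_dict(data: dict) -> SiteArchetype:
    site = SiteArchetype(
        label=data["label"],
        urchins_present=bool(data["urchins_present"]),
        initial=ReefState(**data["initial"]),
        params=SiteParams(**data["params"]),
        area_note=data.get("area_note", ""),
    )
    site.validate()
    return site
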