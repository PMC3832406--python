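"""Synthetic site archetypes for the scenario analysis.

Four archetypes emulate the structure of the Bolinao reef-slope sites the
analysis assumes: two less-degraded sites with sea urchins (lucero_like,
malilnep_like; coral cover near 30%) and two degraded, macroalgae-dominated
sites without urchins (cangaluyan_like near 12%, tomasa_like below 5%).
Initial covers sum to one; fish biomass is low at the degraded sites, whose
recruitment is further constrained by the coral-cover feedback. The default
states and rates are plausible reconstructions of a 2008-like condition,
calibrated so the fixed-schedule bleaching run reproduces the documented
site ordering of post-bleaching cover and recovery (see docs/methods.md);
they are not empirical survey values.

Jitter is multiplicative log-uniform. The jitter factors for a given seed
are drawn identically for every archetype (the archetypes share one factor
stream), so cross-archetype ordering of initial coral cover is preserved at
any jitter amplitude up to the supported 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import ReefState, SiteParams

__all__ = [
    "ARCHETYPE_LABELS",
    "SiteArchetype",
    "make_site",
    "make_degradation_series",
]

ARCHETYPE_LABELS = ("lucero_like", "malilnep_like", "cangaluyan_like", "tomasa_like")

#: Modelled area: the scale at which local marine reserves are implemented.
AREA_NOTE = "500 m x 500 m reef-slope cell"

# Initial states: (coral, eac, macroturf, macroalgae, herb, pisc, urchin).
_INITIAL = {
    "lucero_like": (0.30, 0.52, 0.12, 0.06, 7.0, 1.2, 10.0),
    "malilnep_like": (0.28, 0.51, 0.13, 0.08, 6.0, 1.0, 10.0),
    "cangaluyan_like": (0.12, 0.32, 0.22, 0.34, 2.0, 0.4, 0.0),
    "tomasa_like": (0.03, 0.30, 0.25, 0.42, 1.0, 0.2, 0.0),
}

# Per-archetype parameter overrides on top of the SiteParams defaults.
# Degraded sites support less fish recruitment (poorer habitat quality).
_PARAM_OVERRIDES = {
    "lucero_like": {"urchins_present": True},
    "malilnep_like": {"urchins_present": True, "coral_growth": 0.25},
    "cangaluyan_like": {
        "urchins_present": False,
        "herb_recruit": 2.5,
        "pisc_recruit": 0.5,
        "coral_recruit_ext": 0.008,
    },
    "tomasa_like": {
        "urchins_present": False,
        "herb_recruit": 1.2,
        "pisc_recruit": 0.25,
        "coral_recruit_ext": 0.002,
    },
}


@dataclass
class SiteArchetype:
    """A site fixture: label, initial state and parameterisation."""

    label: str
    urchins_present: bool
    initial: ReefState
    params: SiteParams
    area_note: str = AREA_NOTE

    def validate(self) -> None:
        self.initial.validate()
        self.params.validate()
        if not self.urchins_present and np.any(
            np.asarray(self.initial.urchin_biomass) != 0
        ):
            raise ValueError("urchin biomass must be 0 where urchins are absent")


def _jitter_factors(seed: int | None, jitter: float, n: int) -> np.ndarray:
    """Log-uniform multiplicative factors in [1/(1+jitter), 1+jitter]."""
    if jitter == 0 or seed is None:
        return np.ones(n)
    rng = np.random.default_rng(seed)
    half_width = np.log1p(jitter)
    return np.exp(rng.uniform(-half_width, half_width, size=n))


def _assemble(label: str, values, params: SiteParams,
              seed: int | None, jitter: float) -> SiteArchetype:
    covers = np.asarray(values[:4], dtype=float)
    biomasses = np.asarray(values[4:], dtype=float)
    f = _jitter_factors(seed, jitter, 7)
    covers = covers * f[:4]
    covers = covers / covers.sum()
    biomasses = biomasses * f[4:]
    if not params.urchins_present:
        biomasses[2] = 0.0
    initial = ReefState(
        coral=float(covers[0]),
        eac=float(covers[1]),
        macroturf=float(covers[2]),
        macroalgae=float(covers[3]),
        herbivore_biomass=float(biomasses[0]),
        piscivore_biomass=float(biomasses[1]),
        urchin_biomass=float(biomasses[2]),
    )
    site = SiteArchetype(
        label=label,
        urchins_present=params.urchins_present,
        initial=initial,
        params=params,
    )
    site.validate()
    return site


def make_site(
    archetype_label: str, seed: int | None = None, jitter: float = 0.0
) -> SiteArchetype:
    """Build one site archetype, optionally perturbed.

    ``jitter`` (in [0, 0.5]) perturbs covers and biomasses multiplicatively
    (log-uniform) and renormalises covers to sum to one. Identical seeds
    produce identical jitter factors across archetypes, so the ordering of
    initial coral cover between archetypes is preserved.
    """
    if archetype_label not in ARCHETYPE_LABELS:
        raise ValueError(
            f"unknown archetype {archetype_label!r}; expected one of {ARCHETYPE_LABELS}"
        )
    if not 0.0 <= jitter <= 0.5:
        raise ValueError("jitter must be in [0, 0.5]")
    params = SiteParams(**_PARAM_OVERRIDES[archetype_label])
    return _assemble(archetype_label, _INITIAL[archetype_label], params, seed, jitter)


def make_degradation_series(
    n_sites: int,
    coral_range: tuple[float, float],
    seed: int | None = None,
    jitter: float = 0.0,
) -> list[SiteArchetype]:
    """Sites with initial coral cover evenly spaced across ``coral_range``.

    Supports sensitivity sweeps over initial condition: each site blends
    the degraded (tomasa_like) and healthy (lucero_like) archetype rules
    linearly in target coral cover; urchins follow the healthy archetype
    for covers above the midpoint of the healthy/degraded coral covers.
    """
    lo, hi = coral_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("coral_range must satisfy 0 < lo <= hi < 1")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites == 1:
        targets = [0.5 * (lo + hi)]
    else:
        targets = list(np.linspace(lo, hi, n_sites))

    low_state = np.asarray(_INITIAL["tomasa_like"], dtype=float)
    high_state = np.asarray(_INITIAL["lucero_like"], dtype=float)
    c_low, c_high = low_state[0], high_state[0]

    sites = []
    for i, target in enumerate(targets):
        w = np.clip((target - c_low) / (c_high - c_low), 0.0, 1.0)
        values = (1 - w) * low_state + w * high_state
        # pin coral at the requested cover; the rest fills the remainder
        rest = values[1:4] / values[1:4].sum() * (1.0 - target)
        values = np.concatenate([[target], rest, values[4:]])
        urchins = w >= 0.5
        params = SiteParams(
            urchins_present=bool(urchins),
            herb_recruit=float((1 - w) * 1.2 + w * 3.0),
            pisc_recruit=float((1 - w) * 0.25 + w * 0.6),
        )
        child = None if seed is None else seed + i
        sites.append(_assemble(f"series_{i:02d}", values, params, child, jitter))
    return sites
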