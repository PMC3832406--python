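"""Stressor forcings: nutrification, sedimentation, fishing and bleaching.

Nutrification and sedimentation jointly represent water quality (both
originate predominantly from aquaculture, so they are always present or
absent together). They act by rescaling site parameters: nutrification
raises macroturf and macroalgal growth; sedimentation depresses coral
growth and recruitment, raises coral mortality, and blocks coral
recruitment onto macroturf. Fishing is a constant-rate extraction (a catch
quantity, t km^-2 yr^-1, equal numerically to g m^-2 yr^-1) split between
herbivorous and piscivorous fish in the observed catch composition.
Bleaching is an instantaneous proportional loss of coral cover, either on a
fixed schedule or drawn year-by-year at a stated long-run frequency.

Ranged forcing magnitudes are drawn uniformly once per replicate run, which
is the model's stochastic element; bleaching severity is drawn per event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import DAYS_PER_YEAR, ReefState, SiteParams, Trajectory, simulate

__all__ = [
    "NutrientForcing",
    "SedimentForcing",
    "BleachingRegime",
    "FishingRegime",
    "ForcingSet",
    "HERBIVORE_CATCH_SHARE",
    "PISCIVORE_CATCH_SHARE",
    "draw_forcings",
    "apply_water_quality",
    "schedule_bleaching",
    "apply_bleaching_event",
    "extraction_rates",
    "simulate_forced",
]

# Observed catch composition on the modelled reefs.
HERBIVORE_CATCH_SHARE = 0.683
PISCIVORE_CATCH_SHARE = 0.317

# Literature ranges for the water-quality parameter scalings.
TURF_GROWTH_SCALE_RANGE = (1.3, 2.0)
MACROALGAE_GROWTH_SCALE_RANGE = (2.0, 7.0)
CORAL_GROWTH_REDUCTION_RANGE = (0.0, 0.3)
CORAL_RECRUIT_REDUCTION_RANGE = (0.0, 0.6)
CORAL_MORTALITY_INCREASE_RANGE = (0.0, 0.2)
BLEACHING_SEVERITY_RANGE = (0.1, 0.6)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class NutrientForcing:
    """Nutrification: multiplicative boost to algal growth rates."""

    turf_growth_scale: float
    macroalgae_growth_scale: float

    def __post_init__(self):
        # draws come from the literature ranges; the identity value 1.0
        # (no effect) is additionally admitted for each scale
        _check_range("turf_growth_scale", self.turf_growth_scale,
                     1.0, TURF_GROWTH_SCALE_RANGE[1])
        _check_range("macroalgae_growth_scale", self.macroalgae_growth_scale,
                     1.0, MACROALGAE_GROWTH_SCALE_RANGE[1])


@dataclass(frozen=True)
class SedimentForcing:
    """Sedimentation: fractional depression of coral demographics."""

    coral_growth_reduction: float
    coral_recruit_reduction: float
    coral_mortality_increase: float
    block_recruitment_on_macroturf: bool = True

    def __post_init__(self):
        _check_range("coral_growth_reduction", self.coral_growth_reduction,
                     *CORAL_GROWTH_REDUCTION_RANGE)
        _check_range("coral_recruit_reduction", self.coral_recruit_reduction,
                     *CORAL_RECRUIT_REDUCTION_RANGE)
        _check_range("coral_mortality_increase", self.coral_mortality_increase,
                     *CORAL_MORTALITY_INCREASE_RANGE)


@dataclass(frozen=True)
class BleachingRegime:
    """Bleaching frequency/severity specification for a scenario.

    ``stochastic`` mode makes each year an event with probability
    frequency_per_decade/10 and draws severity uniformly from
    ``severity_range``; ``fixed`` mode uses ``fixed_schedule`` verbatim.
    """

    frequency_per_decade: int = 0
    severity_range: tuple[float, float] = BLEACHING_SEVERITY_RANGE
    mode: str = "stochastic"
    fixed_schedule: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        if self.mode not in ("stochastic", "fixed"):
            raise ValueError(f"unknown bleaching mode {self.mode!r}")
        if self.frequency_per_decade not in (0, 1, 2):
            raise ValueError("frequency_per_decade must be 0, 1 or 2")


@dataclass(frozen=True)
class FishingRegime:
    """Total extraction rate range (t km^-2 yr^-1) and catch composition."""

    total_rate_range: tuple[float, float] = (0.0, 0.0)
    herbivore_share: float = HERBIVORE_CATCH_SHARE
    piscivore_share: float = PISCIVORE_CATCH_SHARE

    def __post_init__(self):
        lo, hi = self.total_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("total_rate_range must be 0 <= lo <= hi")
        if abs(self.herbivore_share + self.piscivore_share - 1.0) > 1e-9:
            raise ValueError("catch shares must sum to 1")


@dataclass
class ForcingSet:
    """Realised stressor magnitudes for one replicate run.

    ``nutrient`` and ``sediment`` are jointly present (poor water quality)
    or jointly ``None`` (regulated water quality). The bleaching regime is
    realised as an explicit (event_year, severity) schedule.
    """

    fishing_total: float = 0.0            # realised t km^-2 yr^-1
    nutrient: NutrientForcing | None = None
    sediment: SedimentForcing | None = None
    bleaching_schedule: tuple[tuple[int, float], ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if (self.nutrient is None) != (self.sediment is None):
            raise ValueError(
                "nutrification and sedimentation must be jointly present or absent"
            )

    @property
    def water_quality_poor(self) -> bool:
        return self.nutrient is not None


def _draw_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Uniform draw from a closed range; a degenerate range collapses to lo."""
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def draw_forcings(
    scenario,
    rng_seed: int,
    horizon_years: int = 40,
    *,
    turf_growth_scale_range: tuple[float, float] = TURF_GROWTH_SCALE_RANGE,
    macroalgae_growth_scale_range: tuple[float, float] = MACROALGAE_GROWTH_SCALE_RANGE,
    coral_growth_reduction_range: tuple[float, float] = CORAL_GROWTH_REDUCTION_RANGE,
    coral_recruit_reduction_range: tuple[float, float] = CORAL_RECRUIT_REDUCTION_RANGE,
    coral_mortality_increase_range: tuple[float, float] = CORAL_MORTALITY_INCREASE_RANGE,
) -> ForcingSet:
    """Realise one replicate's stressor magnitudes for ``scenario``.

    Each ranged quantity is drawn uniformly once per run; the bleaching
    regime is realised into an explicit event schedule. The draw order is
    fixed (fishing, water quality, bleaching) so results are reproducible
    from the seed alone. The keyword range overrides narrow the literature
    ranges, e.g. for sensitivity runs.
    """
    rng = np.random.default_rng(rng_seed)
    fishing_total = _draw_uniform(rng, *scenario.fishing.total_rate_range)

    nutrient = sediment = None
    if scenario.water_quality_poor:
        nutrient = NutrientForcing(
            turf_growth_scale=_draw_uniform(rng, *turf_growth_scale_range),
            macroalgae_growth_scale=_draw_uniform(rng, *macroalgae_growth_scale_range),
        )
        sediment = SedimentForcing(
            coral_growth_reduction=_draw_uniform(rng, *coral_growth_reduction_range),
            coral_recruit_reduction=_draw_uniform(rng, *coral_recruit_reduction_range),
            coral_mortality_increase=_draw_uniform(rng, *coral_mortality_increase_range),
        )

    schedule = schedule_bleaching(scenario.bleaching, horizon_years, rng)
    return ForcingSet(
        fishing_total=fishing_total,
        nutrient=nutrient,
        sediment=sediment,
        bleaching_schedule=schedule,
        seed=rng_seed,
    )


def apply_water_quality(
    params: SiteParams, nf: NutrientForcing, sf: SedimentForcing
) -> SiteParams:
    """Fold the realised water-quality scalars into a parameter set.

    Returns a new :class:`SiteParams` with algal growth scaled up, coral
    growth/recruitment scaled down, coral mortality raised, and coral
    settlement on macroturf disabled. The returned set is flagged so a
    second application is rejected (the forcing acts exactly once per run).
    """
    if params.water_quality_applied:
        raise ValueError("water quality forcing already applied to this parameter set")
    g = 1.0 - sf.coral_growth_reduction
    r = 1.0 - sf.coral_recruit_reduction
    return params.copy(
        turf_emergence=params.turf_emergence * nf.turf_growth_scale,
        macroalgae_growth=params.macroalgae_growth * nf.macroalgae_growth_scale,
        coral_growth=params.coral_growth * g,
        coral_recruit_ext=params.coral_recruit_ext * r,
        coral_recruit_endo=params.coral_recruit_endo * r,
        coral_mortality=params.coral_mortality + sf.coral_mortality_increase,
        allow_turf_settlement=not sf.block_recruitment_on_macroturf,
        water_quality_applied=True,
    )


def schedule_bleaching(
    regime: BleachingRegime,
    horizon_years: int,
    rng: np.random.Generator | int,
) -> tuple[tuple[int, float], ...]:
    """Realise a bleaching regime into an explicit (event_year, severity) list.

    Stochastic mode: each year 1..horizon is an event with probability
    frequency_per_decade/10 (a Bernoulli reading of the stated long-run
    frequency), with severity drawn uniformly per event. Fixed mode returns
    the configured schedule verbatim after checking it fits the horizon.
    """
    if horizon_years < 0:
        raise ValueError("horizon_years must be >= 0")
    if regime.mode == "fixed":
        for year, severity in regime.fixed_schedule:
            if year > horizon_years:
                raise ValueError(
                    f"fixed bleaching event at year {year} beyond horizon {horizon_years}"
                )
            if not 0.0 <= severity <= 1.0:
                raise ValueError(f"severity {severity} outside [0, 1]")
        return tuple(regime.fixed_schedule)

    if regime.frequency_per_decade == 0:
        return ()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = regime.frequency_per_decade / 10.0
    lo, hi = regime.severity_range
    events = []
    for year in range(1, horizon_years + 1):
        if rng.random() < p:
            events.append((year, float(rng.uniform(lo, hi))))
    return tuple(events)


def apply_bleaching_event(state: ReefState, severity: float) -> ReefState:
    """Remove ``severity`` of the live coral cover, transferring it to EAC."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity {severity} outside [0, 1]")
    lost = state.coral * severity
    return replace(state, coral=state.coral - lost, eac=state.eac + lost)


def extraction_rates(
    regime: FishingRegime, realised_total: float
) -> tuple[float, float]:
    """Split a realised total catch into per-group daily extraction rates.

    Input is t km^-2 yr^-1 (numerically g m^-2 yr^-1); output is
    (herbivore, piscivore) in g m^-2 day^-1.
    """
    if realised_total < 0:
        raise ValueError("extraction rate must be >= 0")
    lo, hi = regime.total_rate_range
    if not (lo - 1e-12) <= realised_total <= (hi + 1e-12):
        raise ValueError(
            f"realised total {realised_total} outside regime range [{lo}, {hi}]"
        )
    herb = regime.herbivore_share * realised_total / DAYS_PER_YEAR
    pisc = regime.piscivore_share * realised_total / DAYS_PER_YEAR
    return herb, pisc


def simulate_forced(
    initial: ReefState,
    params: SiteParams,
    forcing: ForcingSet,
    horizon_years: int,
    seed: int | None = None,
) -> Trajectory:
    """Run the daily model under a realised forcing set.

    Applies the water-quality parameter scalings (if poor water quality),
    converts the realised catch into constant annual extraction rates, and
    hands the bleaching schedule to the simulator.
    """
    if forcing.water_quality_poor:
        params = apply_water_quality(params, forcing.nutrient, forcing.sediment)
    herb = HERBIVORE_CATCH_SHARE * forcing.fishing_total
    pisc = PISCIVORE_CATCH_SHARE * forcing.fishing_total
    return simulate(
        initial,
        params,
        extraction=(herb, pisc),
        bleaching_schedule=forcing.bleaching_schedule,
        horizon_years=horizon_years,
        seed=seed,
        forcing=forcing,
    )
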