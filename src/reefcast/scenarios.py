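"""Factorial scenario grid and seeded Monte-Carlo ensembles.

A scenario is one cell of the fishing x bleaching x water-quality
factorial (3 x 3 x 2 = 18 cells by default). Each scenario x site
combination is simulated as an ensemble of replicate runs (20 by default);
replicates differ only in their stochastic forcing draws, seeded from a
deterministic tree so any single replicate is reproducible without
re-running the grid. Snapshot community matrices (runs x state variables
at a chosen year) are the unit of all downstream multivariate analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    DAYS_PER_YEAR,
    STATE_VARIABLES,
    ReefState,
    SiteParams,
    Trajectory,
    simulate,
)
from .forcings import (
    HERBIVORE_CATCH_SHARE,
    PISCIVORE_CATCH_SHARE,
    BleachingRegime,
    FishingRegime,
    ForcingSet,
    apply_water_quality,
    draw_forcings,
)
from .sites import SiteArchetype

__all__ = [
    "FISHING_LEVELS",
    "BLEACHING_LEVELS",
    "WATER_QUALITY_LEVELS",
    "Scenario",
    "EnsembleResult",
    "CommunityMatrix",
    "build_scenario_grid",
    "default_grid",
    "child_seed",
    "run_ensemble",
    "snapshot_matrix",
    "fixed_bleaching_regime",
]

#: Fishing levels: total extraction ranges in t km^-2 yr^-1.
FISHING_LEVELS = {
    "none": (0.0, 0.0),            # no-take reserve
    "moderate": (1.3, 1.4),        # 50% of current yield
    "high": (2.6, 2.8),            # current yield
}

#: Bleaching levels: long-run event frequency per decade.
BLEACHING_LEVELS = {"none": 0, "once-per-decade": 1, "twice-per-decade": 2}

#: Water-quality levels: is nutrification-sedimentation present?
WATER_QUALITY_LEVELS = {"regulated": False, "unregulated": True}

#: The fixed schedule used for trajectory/recovery analysis: a severe event
#: at year 20 (30% of cover lost) and a milder one at year 38 (15%).
FIXED_BLEACHING_SCHEDULE = ((20, 0.30), (38, 0.15))


def fixed_bleaching_regime() -> BleachingRegime:
    return BleachingRegime(mode="fixed", fixed_schedule=FIXED_BLEACHING_SCHEDULE)


@dataclass(frozen=True)
class Scenario:
    """One cell of the fishing x bleaching x water-quality factorial."""

    fishing_level: str
    bleaching_level: str
    water_quality: str

    def __post_init__(self):
        if self.fishing_level not in FISHING_LEVELS:
            raise ValueError(f"unknown fishing level {self.fishing_level!r}")
        if self.bleaching_level not in BLEACHING_LEVELS:
            raise ValueError(f"unknown bleaching level {self.bleaching_level!r}")
        if self.water_quality not in WATER_QUALITY_LEVELS:
            raise ValueError(f"unknown water-quality level {self.water_quality!r}")

    @property
    def label(self) -> str:
        return f"F={self.fishing_level}|B={self.bleaching_level}|WQ={self.water_quality}"

    @property
    def fishing(self) -> FishingRegime:
        return FishingRegime(total_rate_range=FISHING_LEVELS[self.fishing_level])

    @property
    def bleaching(self) -> BleachingRegime:
        return BleachingRegime(frequency_per_decade=BLEACHING_LEVELS[self.bleaching_level])

    @property
    def water_quality_poor(self) -> bool:
        return WATER_QUALITY_LEVELS[self.water_quality]


def build_scenario_grid(
    fishing_levels=("none", "moderate", "high"),
    bleaching_levels=("none", "once-per-decade", "twice-per-decade"),
    water_levels=("regulated", "unregulated"),
) -> list[Scenario]:
    """Full factorial of the given levels, in stable deterministic order
    (water quality outermost, then fishing, then bleaching)."""
    for name, levels in (
        ("fishing", fishing_levels),
        ("bleaching", bleaching_levels),
        ("water quality", water_levels),
    ):
        if len(levels) == 0:
            raise ValueError(f"{name} level list is empty")
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate {name} levels: {levels}")
    return [
        Scenario(fishing_level=f, bleaching_level=b, water_quality=w)
        for w, f, b in itertools.product(water_levels, fishing_levels, bleaching_levels)
    ]


def default_grid() -> list[Scenario]:
    """The 18-scenario grid of the standard analysis."""
    return build_scenario_grid()


def child_seed(master_seed: int, scenario_index: int, replicate: int) -> int:
    """Pure child-seed derivation for one replicate of one scenario.

    Uses numpy's SeedSequence spawn-key mechanism, truncated below 2^31 so
    the value round-trips through any integer seed interface.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(scenario_index, replicate))
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF)


@dataclass
class EnsembleResult:
    """Replicate trajectories for one scenario x site.

    ``trajectory.states`` has shape (n_days + 1, n_replicates, 7); all
    replicates share the daily time axis.
    """

    scenario: Scenario
    site_label: str
    trajectory: Trajectory
    forcing_sets: list[ForcingSet]
    replicate_seeds: list[int]
    urchins_present: bool = True

    @property
    def n_replicates(self) -> int:
        return self.trajectory.states.shape[1]

    def replicate(self, i: int) -> Trajectory:
        return Trajectory(
            days=self.trajectory.days,
            states=self.trajectory.states[:, i, :],
            seed=self.replicate_seeds[i],
            forcing=self.forcing_sets[i],
        )

    def mean_trajectory(self) -> Trajectory:
        """Ensemble-mean trajectory (arithmetic mean over replicates)."""
        return Trajectory(
            days=self.trajectory.days,
            states=self.trajectory.states.mean(axis=1),
        )

    def snapshot(self, year: int) -> np.ndarray:
        """Replicate states at the end of ``year`` (day year*365); shape (n, 7)."""
        day = int(year) * DAYS_PER_YEAR
        if day >= self.trajectory.states.shape[0]:
            raise ValueError(f"year {year} beyond simulated horizon")
        return self.trajectory.states[day]


def _stack_params(base: SiteParams, forcing_sets: list[ForcingSet]) -> SiteParams:
    """Per-replicate water-quality application, stacked into array fields."""
    poor = [fs.water_quality_poor for fs in forcing_sets]
    if not any(poor):
        return base
    if not all(poor):
        raise ValueError("replicates of one scenario must share the water-quality level")
    applied = [apply_water_quality(base, fs.nutrient, fs.sediment) for fs in forcing_sets]
    return base.copy(
        turf_emergence=np.array([p.turf_emergence for p in applied]),
        macroalgae_growth=np.array([p.macroalgae_growth for p in applied]),
        coral_growth=np.array([p.coral_growth for p in applied]),
        coral_recruit_ext=np.array([p.coral_recruit_ext for p in applied]),
        coral_recruit_endo=np.array([p.coral_recruit_endo for p in applied]),
        coral_mortality=np.array([p.coral_mortality for p in applied]),
        allow_turf_settlement=False,
        water_quality_applied=True,
    )


def run_ensemble(
    scenario: Scenario,
    site: SiteArchetype,
    n_replicates: int = 20,
    master_seed: int = 0,
    horizon_years: int = 40,
    scenario_index: int = 0,
    bleaching_override: BleachingRegime | None = None,
) -> EnsembleResult:
    """Run a seeded Monte-Carlo ensemble for one scenario at one site.

    Replicate i draws its forcing set from ``child_seed(master_seed,
    scenario_index, i)``; all replicates start from the site's initial
    state and advance together in one vectorised sweep, which is
    bit-identical to running each replicate alone. ``bleaching_override``
    substitutes a fixed-schedule regime (used for trajectory/recovery
    analysis) for the scenario's stochastic one.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [child_seed(master_seed, scenario_index, i) for i in range(n_replicates)]

    if bleaching_override is not None:
        eff_scenario = _ScenarioWithRegime(scenario, bleaching_override)
    else:
        eff_scenario = scenario
    forcing_sets = [
        draw_forcings(eff_scenario, s, horizon_years=horizon_years) for s in seeds
    ]

    params = _stack_params(site.params, forcing_sets)
    totals = np.array([fs.fishing_total for fs in forcing_sets])
    extraction = (HERBIVORE_CATCH_SHARE * totals, PISCIVORE_CATCH_SHARE * totals)

    # merge per-replicate bleaching schedules into per-event severity arrays
    events: dict[int, np.ndarray] = {}
    for i, fs in enumerate(forcing_sets):
        for year, severity in fs.bleaching_schedule:
            arr = events.setdefault(int(year), np.zeros(n_replicates))
            arr[i] = 1.0 - (1.0 - arr[i]) * (1.0 - severity)
    schedule = sorted(events.items())

    n = n_replicates
    initial = ReefState(
        coral=np.full(n, site.initial.coral),
        eac=np.full(n, site.initial.eac),
        macroturf=np.full(n, site.initial.macroturf),
        macroalgae=np.full(n, site.initial.macroalgae),
        herbivore_biomass=np.full(n, site.initial.herbivore_biomass),
        piscivore_biomass=np.full(n, site.initial.piscivore_biomass),
        urchin_biomass=np.full(n, site.initial.urchin_biomass),
    )
    traj = simulate(
        initial,
        params,
        extraction=extraction,
        bleaching_schedule=schedule,
        horizon_years=horizon_years,
        seed=master_seed,
    )
    return EnsembleResult(
        scenario=scenario,
        site_label=site.label,
        trajectory=traj,
        forcing_sets=forcing_sets,
        replicate_seeds=seeds,
        urchins_present=site.urchins_present,
    )


class _ScenarioWithRegime:
    """Scenario view with a substituted bleaching regime (fixed schedules)."""

    def __init__(self, scenario: Scenario, regime: BleachingRegime):
        self._scenario = scenario
        self.bleaching = regime

    def __getattr__(self, name):
        return getattr(self._scenario, name)


@dataclass
class CommunityMatrix:
    """Runs x state-variables snapshot, the unit of multivariate analysis.

    ``data``: numeric DataFrame, covers in % and biomasses in g m^-2 (the
    urchin column is omitted for sites without urchins). ``groups``: one
    row per run with the three scenario factors, scenario label and
    replicate index.
    """

    data: pd.DataFrame
    groups: pd.DataFrame
    year: int
    site_label: str
    normalised: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.data)


def snapshot_matrix(ensembles: list[EnsembleResult], year: int) -> CommunityMatrix:
    """Extract the community matrix at ``year`` from a list of ensembles.

    One row per replicate per scenario; benthic covers are reported in %
    (x100) and biomasses in g m^-2. All ensembles must come from the same
    site. Extraction reads the stored trajectories and never mutates them.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    site_labels = {e.site_label for e in ensembles}
    if len(site_labels) > 1:
        raise ValueError(f"cannot mix sites in one community matrix: {site_labels}")
    urchins = {e.urchins_present for e in ensembles}
    with_urchins = urchins.pop()

    columns = list(STATE_VARIABLES) if with_urchins else list(STATE_VARIABLES[:-1])
    rows, grouping = [], []
    for ens in ensembles:
        snap = ens.snapshot(year)
        for i in range(ens.n_replicates):
            values = snap[i]
            record = dict(zip(STATE_VARIABLES, values))
            for cover in STATE_VARIABLES[:4]:
                record[cover] *= 100.0
            if not with_urchins:
                record.pop("urchin_biomass")
            rows.append(record)
            grouping.append(
                {
                    "scenario": ens.scenario.label,
                    "fishing": ens.scenario.fishing_level,
                    "bleaching": ens.scenario.bleaching_level,
                    "water_quality": ens.scenario.water_quality,
                    "replicate": i,
                }
            )
    data = pd.DataFrame(rows, columns=columns)
    groups = pd.DataFrame(grouping)
    return CommunityMatrix(
        data=data,
        groups=groups,
        year=year,
        site_label=site_labels.pop(),
        normalised=False,
    )
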