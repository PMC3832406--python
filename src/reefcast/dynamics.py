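"""Daily difference-equation dynamics of a shallow coral-reef community.

The model tracks the proportional cover of four benthic functional groups
(hard coral, grazed epilithic algal community (EAC), macroturf, macroalgae;
covers sum to one, with EAC doubling as the colonisable substrate) and the
biomass (g m^-2) of three consumer groups (herbivorous fish, piscivorous
fish, grazing sea urchins). All process rates are annual; the update
interval is one day, so each step advances the state by dt/365 of a year.

Benthic transfers are zero-sum mass-action exchanges between cover pools:

* coral grows laterally onto EAC and recruits onto colonisable substrate
  (EAC, plus macroturf unless sediment blocks settlement), with recruitment
  split into an endogenous part proportional to local cover and a constant
  external larval supply;
* coral suffers natural mortality (back to EAC) and is overgrown by
  macroalgae and, more weakly, by dense macroturf;
* ungrazed fine turf on EAC exerts a constant growth pressure towards
  macroturf; grazing by herbivorous fish and urchins crops macroturf and
  macroalgae back to EAC; macroturf matures into macroalgae, and macroalgae
  spreads vegetatively onto EAC.

Consumer biomass changes by recruitment (scaled for fish by a coral-cover
dependent multiplier, reflecting the dependence of fish recruits on live
coral habitat), assimilated grazing/predation intake, natural mortality,
piscivory on herbivores, and fishing extraction. Removals are truncated so
biomass never goes negative; likewise every benthic pool scales its total
outflow so cover never goes negative, which keeps the cover sum exactly
conserved.

All state components may be scalars or equal-shape numpy arrays, so an
ensemble of replicates (with per-replicate parameter draws) advances in a
single vectorised sweep; elementwise IEEE arithmetic makes a replicate of a
vectorised run bit-identical to the same replicate run alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "STATE_VARIABLES",
    "ReefState",
    "SiteParams",
    "Trajectory",
    "fish_recruitment_multiplier",
    "step",
    "simulate",
]

#: Canonical ordering of the seven state variables.
STATE_VARIABLES = (
    "coral",
    "eac",
    "macroturf",
    "macroalgae",
    "herbivore_biomass",
    "piscivore_biomass",
    "urchin_biomass",
)

DAYS_PER_YEAR = 365
COVER_SUM_TOL = 1e-9


class InvalidStateError(ValueError):
    """Raised when a reef state violates a structural invariant."""


@dataclass
class ReefState:
    """Reef state at one instant: benthic covers (proportions) and consumer
    biomasses (g m^-2)."""

    coral: float | np.ndarray
    eac: float | np.ndarray
    macroturf: float | np.ndarray
    macroalgae: float | np.ndarray
    herbivore_biomass: float | np.ndarray
    piscivore_biomass: float | np.ndarray
    urchin_biomass: float | np.ndarray = 0.0

    def as_array(self) -> np.ndarray:
        """Stack the seven variables along a trailing axis."""
        return np.stack(
            [np.asarray(getattr(self, name), dtype=float) for name in STATE_VARIABLES],
            axis=-1,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ReefState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] != len(STATE_VARIABLES):
            raise ValueError(f"expected trailing axis of length 7, got {arr.shape}")
        return cls(*(arr[..., i] for i in range(len(STATE_VARIABLES))))

    @property
    def covers(self) -> np.ndarray:
        return self.as_array()[..., :4]

    def validate(self) -> None:
        """Check the structural invariants, raising :class:`InvalidStateError`
        with the name of the violated invariant."""
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError("state contains non-finite values")
        for name in STATE_VARIABLES:
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise InvalidStateError(f"negative value in '{name}'")
        total = arr[..., :4].sum(axis=-1)
        if np.any(np.abs(total - 1.0) > COVER_SUM_TOL):
            worst = float(np.max(np.abs(total - 1.0)))
            raise InvalidStateError(
                f"benthic covers must sum to 1 (max deviation {worst:.3e})"
            )


@dataclass
class SiteParams:
    """Site-level rate parameters. All rates are annual (yr^-1) unless noted.

    Grazing coefficients are per unit grazer biomass (yr^-1 per g m^-2);
    grazing on EAC crops fine turf without a cover transfer, while grazing
    on macroturf and macroalgae returns cover to EAC. ``algal_yield``
    converts a unit of grazed cover into assimilable food biomass
    (g m^-2 per unit cover); assimilation efficiencies are dimensionless.
    """

    # -- benthic processes ------------------------------------------------
    coral_growth: float = 0.26         # lateral growth onto EAC, per unit EAC
    coral_mortality: float = 0.04
    coral_crowding: float = 0.20       # density-dependent coral mortality, per unit coral
    coral_recruit_ext: float = 0.004   # external larval supply, per unit substrate
    coral_recruit_endo: float = 0.03   # endogenous recruitment, per unit substrate per unit coral
    turf_emergence: float = 1.4        # EAC -> macroturf growth pressure
    turf_senescence: float = 0.50      # macroturf die-back to EAC
    turf_to_macroalgae: float = 0.02   # macroturf maturation into macroalgae
    macroalgae_growth: float = 3.2    # vegetative spread onto EAC, per unit macroalgae
    macroalgae_senescence: float = 1.0  # macroalgal die-back/dislodgement to EAC
    macroalgae_overgrowth: float = 0.7  # overgrowth of coral, per unit macroalgae
    turf_overgrowth: float = 0.05      # overgrowth of coral by dense turf, per unit turf
    # -- grazing (per g m^-2 of grazer) -----------------------------------
    graze_herb_eac: float = 0.8
    graze_herb_turf: float = 0.30
    graze_herb_macroalgae: float = 0.10
    graze_urchin_eac: float = 0.10
    graze_urchin_turf: float = 0.02
    graze_urchin_macroalgae: float = 0.02
    # -- consumers ---------------------------------------------------------
    algal_yield: float = 6.0           # g m^-2 food per unit grazed cover
    assim_herb: float = 0.21
    assim_pisc: float = 0.3
    herb_recruit: float = 5.0          # g m^-2 yr^-1 at saturating coral cover
    pisc_recruit: float = 1.2
    herb_mortality: float = 1.0
    pisc_mortality: float = 0.4
    piscivory: float = 0.05            # yr^-1 per g m^-2 of piscivore
    urchin_growth: float = 0.2         # logistic self-regulation rate
    urchin_capacity: float = 10.0      # g m^-2
    # -- coral-dependent fish recruitment feedback -------------------------
    recruit_floor: float = 0.1         # r_min: multiplier at zero coral cover
    recruit_saturation: float = 0.3    # c_ref: cover at which the multiplier saturates
    # -- structure flags ---------------------------------------------------
    urchins_present: bool = True
    allow_turf_settlement: bool = True  # sediment forcing disables this
    water_quality_applied: bool = False  # guard: forcing applied at most once

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool):
                continue
            if np.any(np.asarray(value) < 0):
                raise ValueError(f"parameter '{f.name}' must be non-negative")
        if np.any(np.asarray(self.recruit_floor) > 1):
            raise ValueError("recruit_floor must be <= 1")
        if np.any(np.asarray(self.recruit_saturation) <= 0):
            raise ValueError("recruit_saturation must be > 0")

    def copy(self, **changes) -> "SiteParams":
        return replace(self, **changes)

    def zeroed(self) -> "SiteParams":
        """All rates set to zero (fixed-point parameterisation, used in tests)."""
        changes = {
            f.name: 0.0
            for f in fields(self)
            if not isinstance(getattr(self, f.name), bool)
        }
        # keep denominators of scaling terms non-zero
        changes["recruit_saturation"] = self.recruit_saturation
        changes["urchin_capacity"] = self.urchin_capacity
        return replace(self, **changes)


@dataclass
class Trajectory:
    """A simulated run: daily states from day 0 to horizon_years*365.

    ``states`` has shape (n_days + 1, ..., 7) in :data:`STATE_VARIABLES`
    order; ``days`` is the matching integer time axis.
    """

    days: np.ndarray
    states: np.ndarray
    seed: int | None = None
    forcing: object | None = None

    def __len__(self) -> int:
        return self.states.shape[0]

    def variable(self, name: str) -> np.ndarray:
        return self.states[..., STATE_VARIABLES.index(name)]

    @property
    def coral(self) -> np.ndarray:
        return self.variable("coral")

    def state_at(self, day: int) -> ReefState:
        return ReefState.from_array(self.states[day])

    def final_state(self) -> ReefState:
        return ReefState.from_array(self.states[-1])


def fish_recruitment_multiplier(
    coral_cover: float | np.ndarray,
    r_min: float | np.ndarray,
    c_ref: float | np.ndarray,
) -> float | np.ndarray:
    """Coral-cover dependent scaling of fish recruitment.

    Rises piecewise-linearly from ``r_min`` at zero coral cover to 1 at
    cover ``c_ref``, and saturates at 1 above that. Represents the habitat
    dependence of settling reef fish on live coral.
    """
    if np.any(np.asarray(c_ref) <= 0):
        raise ValueError("c_ref must be > 0 (scaling undefined at 0)")
    coral = np.clip(np.asarray(coral_cover, dtype=float), 0.0, None)
    mult = r_min + (1.0 - r_min) * np.minimum(coral, c_ref) / c_ref
    mult = np.minimum(mult, 1.0)  # guard the upper bound against rounding
    if np.ndim(coral_cover) == 0 and np.ndim(r_min) == 0 and np.ndim(c_ref) == 0:
        return float(mult)
    return mult


def _params_tuple(p: SiteParams) -> tuple:
    """Pre-extract parameter arrays for the inner update loop."""
    return (
        np.asarray(p.coral_growth, dtype=float),
        np.asarray(p.coral_mortality, dtype=float),
        np.asarray(p.coral_crowding, dtype=float),
        np.asarray(p.coral_recruit_ext, dtype=float),
        np.asarray(p.coral_recruit_endo, dtype=float),
        np.asarray(p.turf_emergence, dtype=float),
        np.asarray(p.turf_senescence, dtype=float),
        np.asarray(p.turf_to_macroalgae, dtype=float),
        np.asarray(p.macroalgae_growth, dtype=float),
        np.asarray(p.macroalgae_senescence, dtype=float),
        np.asarray(p.macroalgae_overgrowth, dtype=float),
        np.asarray(p.turf_overgrowth, dtype=float),
        np.asarray(p.graze_herb_eac, dtype=float),
        np.asarray(p.graze_herb_turf, dtype=float),
        np.asarray(p.graze_herb_macroalgae, dtype=float),
        np.asarray(p.graze_urchin_eac, dtype=float),
        np.asarray(p.graze_urchin_turf, dtype=float),
        np.asarray(p.graze_urchin_macroalgae, dtype=float),
        np.asarray(p.algal_yield, dtype=float),
        np.asarray(p.assim_herb, dtype=float),
        np.asarray(p.assim_pisc, dtype=float),
        np.asarray(p.herb_recruit, dtype=float),
        np.asarray(p.pisc_recruit, dtype=float),
        np.asarray(p.herb_mortality, dtype=float),
        np.asarray(p.pisc_mortality, dtype=float),
        np.asarray(p.piscivory, dtype=float),
        np.asarray(p.urchin_growth, dtype=float),
        np.asarray(p.urchin_capacity, dtype=float),
        np.asarray(p.recruit_floor, dtype=float),
        np.asarray(p.recruit_saturation, dtype=float),
        1.0 if p.allow_turf_settlement else 0.0,
        bool(p.urchins_present),
    )


def _step_core(C, E, T, M, H, P, U, pr, extract_herb, extract_pisc, dt_yr):
    """One explicit-Euler day. Inputs/outputs are numpy arrays; removals are
    truncated per source pool so covers and biomasses stay non-negative and
    the cover sum is conserved exactly (up to float rounding)."""
    (g_C, m_C, c_C, r_ext, r_endo, gamma, m_T, sigma, g_M, m_M, o_M, o_T,
     k_HE, k_HT, k_HM, k_UE, k_UT, k_UM,
     Y, eps_H, eps_P, rec_H, rec_P, m_H, m_P, pv,
     r_U, K_U, r_min, c_ref, turf_settle, urchins) = pr

    recruit = r_ext + r_endo * C
    # annual flux densities between benthic pools
    f_EC = (g_C * C + recruit) * E          # EAC -> coral
    f_TC = recruit * T * turf_settle        # macroturf -> coral
    f_CE = (m_C + c_C * C) * C              # coral -> EAC (baseline + crowding mortality)
    f_CM = o_M * M * C                      # coral -> macroalgae (overgrowth)
    f_CT = o_T * T * C                      # coral -> macroturf (overgrowth)
    f_ET = gamma * E                        # EAC -> macroturf
    f_EM = g_M * M * E                      # EAC -> macroalgae
    f_TE = (k_HT * H + k_UT * U) * T + m_T * T   # grazing + senescence return turf to EAC
    f_TM = sigma * T                        # turf matures to macroalgae
    f_ME = (k_HM * H + k_UM * U) * M + m_M * M   # grazing + senescence return macroalgae to EAC

    # scale each pool's outflow so it cannot exceed the standing cover
    out_C = (f_CE + f_CM + f_CT) * dt_yr
    out_E = (f_EC + f_ET + f_EM) * dt_yr
    out_T = (f_TC + f_TE + f_TM) * dt_yr
    out_M = f_ME * dt_yr
    s_C = np.where(out_C > C, np.where(out_C > 0, C / np.maximum(out_C, 1e-300), 1.0), 1.0)
    s_E = np.where(out_E > E, np.where(out_E > 0, E / np.maximum(out_E, 1e-300), 1.0), 1.0)
    s_T = np.where(out_T > T, np.where(out_T > 0, T / np.maximum(out_T, 1e-300), 1.0), 1.0)
    s_M = np.where(out_M > M, np.where(out_M > 0, M / np.maximum(out_M, 1e-300), 1.0), 1.0)

    d = dt_yr
    C1 = C - (f_CE + f_CM + f_CT) * d * s_C + (f_EC * s_E + f_TC * s_T) * d
    E1 = E - (f_EC + f_ET + f_EM) * d * s_E + (f_CE * s_C + f_TE * s_T + f_ME * s_M) * d
    T1 = T - (f_TC + f_TE + f_TM) * d * s_T + (f_ET * s_E + f_CT * s_C) * d
    M1 = M - f_ME * d * s_M + (f_CM * s_C + f_EM * s_E + f_TM * s_T) * d
    # a fully drained pool can undershoot zero by one ulp; clamp it
    C1 = np.maximum(C1, 0.0)
    E1 = np.maximum(E1, 0.0)
    T1 = np.maximum(T1, 0.0)
    M1 = np.maximum(M1, 0.0)

    # consumers: recruitment scaled by the coral-cover feedback
    phi = r_min + (1.0 - r_min) * np.minimum(C, c_ref) / c_ref
    food_H = Y * (k_HE * E + k_HT * T + k_HM * M)
    gain_H = (rec_H * phi + eps_H * food_H * H) * d
    loss_H = (m_H + pv * P) * H * d + extract_herb * d
    avail_H = H + gain_H
    s_H = np.where(loss_H > avail_H,
                   avail_H / np.maximum(loss_H, 1e-300), 1.0)
    H1 = np.maximum(avail_H - loss_H * s_H, 0.0)

    pred_realised = pv * P * H * d * s_H
    gain_P = rec_P * phi * d + eps_P * pred_realised
    loss_P = m_P * P * d + extract_pisc * d
    avail_P = P + gain_P
    s_P = np.where(loss_P > avail_P,
                   avail_P / np.maximum(loss_P, 1e-300), 1.0)
    P1 = np.maximum(avail_P - loss_P * s_P, 0.0)

    if urchins:
        U1 = U + r_U * U * (1.0 - U / K_U) * d
        U1 = np.maximum(U1, 0.0)
    else:
        U1 = U * 0.0
    return C1, E1, T1, M1, H1, P1, U1


def step(
    state: ReefState,
    params: SiteParams,
    forcing_today: tuple[float, float] | None = None,
    dt: float = 1.0,
) -> ReefState:
    """Advance the reef state by ``dt`` days (default one day).

    ``forcing_today`` carries the realised daily extraction as a pair of
    annual-equivalent rates (herbivore, piscivore) in g m^-2 yr^-1; water
    quality forcings act through ``params`` (see
    :func:`reefcast.forcings.apply_water_quality`) and bleaching events are
    applied between steps by :func:`simulate`.
    """
    state.validate()
    params.validate()
    fh, fp = (0.0, 0.0) if forcing_today is None else forcing_today
    pr = _params_tuple(params)
    arrs = tuple(np.asarray(getattr(state, name), dtype=float) for name in STATE_VARIABLES)
    out = _step_core(*arrs, pr, np.asarray(fh, dtype=float),
                     np.asarray(fp, dtype=float), dt / DAYS_PER_YEAR)
    scalar = all(np.ndim(getattr(state, name)) == 0 for name in STATE_VARIABLES)
    if scalar:
        out = tuple(float(v) for v in out)
    return ReefState(*out)


def simulate(
    initial: ReefState,
    params: SiteParams,
    extraction: tuple[float, float] = (0.0, 0.0),
    bleaching_schedule: Sequence[tuple[int, float]] = (),
    horizon_years: int = 40,
    seed: int | None = None,
    forcing: object | None = None,
) -> Trajectory:
    """Run the daily model for ``horizon_years`` years.

    ``extraction`` is the realised fishing removal (herbivore, piscivore) in
    g m^-2 yr^-1, constant through the run. ``bleaching_schedule`` is a list
    of (event_year, severity) pairs; each event removes the given fraction
    of coral cover instantaneously at the start of its event day (the lost
    cover becomes EAC) before that day's update. The daily update itself is
    deterministic — all stochasticity lives in the realised forcing draws —
    so identical inputs yield bit-identical trajectories; ``seed`` and
    ``forcing`` are recorded on the trajectory for provenance.
    """
    if horizon_years < 0:
        raise ValueError("horizon_years must be >= 0")
    initial.validate()
    params.validate()
    for year, severity in bleaching_schedule:
        sev = np.asarray(severity)
        if np.any(sev < 0) or np.any(sev > 1):
            raise ValueError(f"bleaching severity {severity} outside [0, 1]")
        if year > horizon_years:
            raise ValueError(
                f"bleaching event at year {year} beyond horizon {horizon_years}"
            )

    fh = np.asarray(extraction[0], dtype=float)
    fp = np.asarray(extraction[1], dtype=float)
    pr = _params_tuple(params)
    dt_yr = 1.0 / DAYS_PER_YEAR

    arrs = [np.asarray(getattr(initial, name), dtype=float) for name in STATE_VARIABLES]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    state = tuple(np.broadcast_to(a, shape).astype(float) for a in arrs)

    n_days = horizon_years * DAYS_PER_YEAR
    out = np.empty((n_days + 1,) + shape + (len(STATE_VARIABLES),), dtype=float)
    for i, a in enumerate(state):
        out[0, ..., i] = a

    events: dict[int, float] = {}
    for year, severity in bleaching_schedule:
        day = int(year) * DAYS_PER_YEAR
        # two events in the same year compound multiplicatively
        events[day] = 1.0 - (1.0 - events.get(day, 0.0)) * (1.0 - severity)

    C, E, T, M, H, P, U = state
    for day in range(1, n_days + 1):
        event_day = day - 1
        if event_day in events:
            lost = C * events[event_day]
            C = C - lost
            E = E + lost
            out[event_day, ..., 0] = C
            out[event_day, ..., 1] = E
        C, E, T, M, H, P, U = _step_core(C, E, T, M, H, P, U, pr, fh, fp, dt_yr)
        out[day, ..., 0] = C
        out[day, ..., 1] = E
        out[day, ..., 2] = T
        out[day, ..., 3] = M
        out[day, ..., 4] = H
        out[day, ..., 5] = P
        out[day, ..., 6] = U

    return Trajectory(days=np.arange(n_days + 1), states=out, seed=seed, forcing=forcing)
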