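"""Unit and property tests for the daily reef dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefcast.dynamics import (
    DAYS_PER_YEAR,
    InvalidStateError,
    ReefState,
    SiteParams,
    fish_recruitment_multiplier,
    simulate,
    step,
)

from conftest import random_valid_state


def oracle_step(state: ReefState, p: SiteParams, extraction=(0.0, 0.0), dt_days=1.0):
    """Independent straight-line re-evaluation of every update term.

    Written as explicit scalar arithmetic, term by term, with its own
    truncation logic; kept deliberately separate from the vectorised
    implementation it checks.
    """
    d = dt_days / 365.0
    C, E, T, M = state.coral, state.eac, state.macroturf, state.macroalgae
    H, P, U = state.herbivore_biomass, state.piscivore_biomass, state.urchin_biomass

    recruit = p.coral_recruit_ext + p.coral_recruit_endo * C
    f_EC = (p.coral_growth * C + recruit) * E
    f_TC = recruit * T if p.allow_turf_settlement else 0.0
    f_CE = (p.coral_mortality + p.coral_crowding * C) * C
    f_CM = p.macroalgae_overgrowth * M * C
    f_CT = p.turf_overgrowth * T * C
    f_ET = p.turf_emergence * E
    f_EM = p.macroalgae_growth * M * E
    f_TE = (p.graze_herb_turf * H + p.graze_urchin_turf * U) * T + p.turf_senescence * T
    f_TM = p.turf_to_macroalgae * T
    f_ME = (p.graze_herb_macroalgae * H + p.graze_urchin_macroalgae * U) * M \
        + p.macroalgae_senescence * M

    def scale(pool, out):
        if out > pool and out > 0:
            return pool / out
        return 1.0

    s_C = scale(C, (f_CE + f_CM + f_CT) * d)
    s_E = scale(E, (f_EC + f_ET + f_EM) * d)
    s_T = scale(T, (f_TC + f_TE + f_TM) * d)
    s_M = scale(M, f_ME * d)

    C1 = C - (f_CE + f_CM + f_CT) * d * s_C + (f_EC * s_E + f_TC * s_T) * d
    E1 = E - (f_EC + f_ET + f_EM) * d * s_E + (f_CE * s_C + f_TE * s_T + f_ME * s_M) * d
    T1 = T - (f_TC + f_TE + f_TM) * d * s_T + (f_ET * s_E + f_CT * s_C) * d
    M1 = M - f_ME * d * s_M + (f_CM * s_C + f_EM * s_E + f_TM * s_T) * d
    C1, E1, T1, M1 = (max(v, 0.0) for v in (C1, E1, T1, M1))

    phi = p.recruit_floor + (1 - p.recruit_floor) * min(C, p.recruit_saturation) \
        / p.recruit_saturation
    food = p.algal_yield * (p.graze_herb_eac * E + p.graze_herb_turf * T
                            + p.graze_herb_macroalgae * M)
    gain_H = (p.herb_recruit * phi + p.assim_herb * food * H) * d
    loss_H = (p.herb_mortality + p.piscivory * P) * H * d + extraction[0] * d
    avail_H = H + gain_H
    s_H = avail_H / loss_H if loss_H > avail_H else 1.0
    H1 = max(avail_H - loss_H * s_H, 0.0)

    pred = p.piscivory * P * H * d * s_H
    gain_P = p.pisc_recruit * phi * d + p.assim_pisc * pred
    loss_P = p.pisc_mortality * P * d + extraction[1] * d
    avail_P = P + gain_P
    s_P = avail_P / loss_P if loss_P > avail_P else 1.0
    P1 = max(avail_P - loss_P * s_P, 0.0)

    if p.urchins_present:
        U1 = max(U + p.urchin_growth * U * (1 - U / p.urchin_capacity) * d, 0.0)
    else:
        U1 = 0.0
    return C1, E1, T1, M1, H1, P1, U1


class TestStep:
    def test_matches_independent_term_oracle(self, healthy_state, default_params):
        got = step(healthy_state, default_params, forcing_today=(1.8441, 0.8559))
        expect = oracle_step(healthy_state, default_params, extraction=(1.8441, 0.8559))
        for name, e in zip(
            ("coral", "eac", "macroturf", "macroalgae",
             "herbivore_biomass", "piscivore_biomass", "urchin_biomass"),
            expect,
        ):
            assert getattr(got, name) == pytest.approx(e, abs=1e-12), name

    def test_oracle_equivalence_on_random_states(self, default_params):
        rng = np.random.default_rng(42)
        for _ in range(50):
            state = random_valid_state(rng)
            extraction = (float(rng.uniform(0, 5)), float(rng.uniform(0, 2)))
            got = step(state, default_params, forcing_today=extraction)
            expect = oracle_step(state, default_params, extraction=extraction)
            assert np.allclose(got.as_array(), np.array(expect), atol=1e-12)

    def test_pure_coral_state_conserves_cover(self):
        state = ReefState(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        out = step(state, SiteParams(urchins_present=False))
        assert abs(float(np.sum(out.covers)) - 1.0) < 1e-15

    def test_zero_rates_is_fixed_point(self, healthy_state, default_params):
        out = step(healthy_state, default_params.zeroed())
        assert np.array_equal(out.as_array(), healthy_state.as_array())

    def test_rejects_bad_cover_sum(self, default_params):
        bad = ReefState(0.5, 0.5, 0.5, 0.0, 1.0, 1.0, 1.0)
        with pytest.raises(InvalidStateError, match="sum to 1"):
            step(bad, default_params)

    def test_rejects_negative_biomass(self, default_params):
        bad = ReefState(0.25, 0.25, 0.25, 0.25, -1.0, 0.0, 0.0)
        with pytest.raises(InvalidStateError, match="herbivore_biomass"):
            step(bad, default_params)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        extraction=st.tuples(st.floats(0, 50), st.floats(0, 20)),
    )
    def test_conservation_and_nonnegativity(self, seed, extraction):
        """Covers sum to 1 within 1e-9 and nothing goes negative, even when
        extraction far exceeds standing stock."""
        rng = np.random.default_rng(seed)
        state = random_valid_state(rng)
        params = SiteParams(
            coral_mortality=float(rng.uniform(0, 0.5)),
            macroalgae_growth=float(rng.uniform(0, 10)),
            turf_emergence=float(rng.uniform(0, 5)),
        )
        out = step(state, params, forcing_today=extraction)
        arr = out.as_array()
        assert np.all(arr >= 0)
        assert abs(float(np.sum(arr[:4])) - 1.0) < 1e-9


class TestRecruitmentMultiplier:
    @pytest.mark.parametrize(
        "cover,r_min,c_ref,expected",
        [
            (0.0, 0.1, 0.3, 0.1),    # floor at zero cover
            (0.3, 0.1, 0.3, 1.0),    # saturation at the reference cover
            (0.5, 0.1, 0.3, 1.0),    # stays saturated above it
            (0.15, 0.1, 0.3, 0.55),  # linear interpolation midpoint
        ],
    )
    def test_values(self, cover, r_min, c_ref, expected):
        assert fish_recruitment_multiplier(cover, r_min, c_ref) == pytest.approx(expected)

    def test_monotone_in_cover(self):
        covers = np.linspace(0, 1, 101)
        vals = fish_recruitment_multiplier(covers, 0.1, 0.3)
        assert np.all(np.diff(vals) >= -1e-15)
        assert np.all((vals >= 0.1) & (vals <= 1.0))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fish_recruitment_multiplier(0.5, 0.1, 0.0)


class TestSimulate:
    def test_zero_horizon_returns_initial(self, healthy_state, default_params):
        traj = simulate(healthy_state, default_params, horizon_years=0)
        assert len(traj) == 1
        assert np.array_equal(traj.states[0], healthy_state.as_array())

    def test_negative_horizon_rejected(self, healthy_state, default_params):
        with pytest.raises(ValueError):
            simulate(healthy_state, default_params, horizon_years=-1)

    def test_deterministic_rerun(self, healthy_state, default_params):
        a = simulate(healthy_state, default_params, extraction=(1.8, 0.8),
                     bleaching_schedule=[(1, 0.3)], horizon_years=2)
        b = simulate(healthy_state, default_params, extraction=(1.8, 0.8),
                     bleaching_schedule=[(1, 0.3)], horizon_years=2)
        assert np.array_equal(a.states, b.states)

    def test_unforced_40y_run_keeps_coral_and_invariants(self, healthy_state,
                                                         default_params):
        """A healthy reef with no stressors persists for 40 years and no
        state among the 14,601 violates an invariant."""
        traj = simulate(healthy_state, default_params, horizon_years=40)
        assert len(traj) == 40 * DAYS_PER_YEAR + 1
        assert traj.coral[-1] > 0
        assert np.all(traj.states >= 0)
        sums = traj.states[:, :4].sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-9

    def test_bleaching_event_applied_before_daily_update(self, healthy_state,
                                                         default_params):
        traj = simulate(healthy_state, default_params.zeroed(),
                        bleaching_schedule=[(1, 0.3)], horizon_years=2)
        day = DAYS_PER_YEAR
        # zero rates: the only change is the event itself
        assert traj.coral[day - 1] == pytest.approx(0.30)
        assert traj.coral[day] == pytest.approx(0.30 * 0.7)
        assert traj.variable("eac")[day] == pytest.approx(0.52 + 0.09)
        assert traj.coral[-1] == pytest.approx(0.21)

    def test_event_beyond_horizon_rejected(self, healthy_state, default_params):
        with pytest.raises(ValueError, match="beyond horizon"):
            simulate(healthy_state, default_params,
                     bleaching_schedule=[(5, 0.3)], horizon_years=2)

    def test_urchins_frozen_when_absent(self, default_params):
        state = ReefState(0.3, 0.5, 0.1, 0.1, 5.0, 1.0, 0.0)
        traj = simulate(state, default_params.copy(urchins_present=False),
                        horizon_years=1)
        assert np.all(traj.variable("urchin_biomass") == 0.0)
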