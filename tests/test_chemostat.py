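"""Chemostat core: concentrations, hazards, stepping, equilibria."""

import math

import numpy as np
import pytest

from defensim.chemostat import (
    DomainError,
    Environment,
    StepSizeError,
    Strategy,
    burst_size_distribution,
    initial_state,
    intracellular_concentration,
    lysis_hazard,
    run_to_equilibrium,
    step,
)


class TestEnvironmentValidation:
    def test_rejects_bad_dilution(self):
        with pytest.raises(DomainError):
            Environment(B=1.5)

    def test_rejects_bad_threshold(self):
        with pytest.raises(DomainError):
            Environment(T=0.0)

    def test_rejects_single_size_class(self):
        with pytest.raises(DomainError):
            Environment(p0=1)

    def test_strategy_domain(self, small_env):
        Strategy(a=0.0, r=0.1).validate(small_env)
        Strategy(a=0.7, r=0.0).validate(small_env)
        with pytest.raises(DomainError):
            Strategy(a=0.2, r=0.0).validate(small_env)  # a below 1-T
        with pytest.raises(DomainError):
            Strategy(a=0.0, r=0.9).validate(small_env)  # r above E


class TestConcentration:
    def test_newborn_at_cap_is_one(self, small_env):
        assert intracellular_concentration(small_env.p0, small_env.Q,
                                           small_env) == 1.0

    def test_no_virus_is_zero(self, small_env):
        assert intracellular_concentration(small_env.p0, 0, small_env) == 0.0

    def test_largest_cell_at_cap(self):
        env = Environment(p0=10, Q=1000)
        rho = intracellular_concentration(19, 1000, env)
        assert rho == pytest.approx(10 / 19)

    def test_monotone_in_load_and_size(self, small_env):
        rows = [
            [intracellular_concentration(p, q, small_env)
             for q in range(small_env.Q + 1)]
            for p in range(small_env.p0, small_env.p_max + 1)
        ]
        arr = np.array(rows)
        assert (np.diff(arr, axis=1) > 0).all()  # increasing in q
        assert (np.diff(arr[:, 1:], axis=0) < 0).all()  # decreasing in p

    def test_out_of_range_rejected(self, small_env):
        with pytest.raises(DomainError):
            intracellular_concentration(small_env.p0 - 1, 0, small_env)
        with pytest.raises(DomainError):
            intracellular_concentration(small_env.p0, small_env.Q + 1, small_env)


class TestLysisHazard:
    def test_zero_at_zero(self, small_env):
        assert lysis_hazard(0.0, small_env) == 0.0

    def test_forced_at_threshold(self, small_env):
        assert math.isinf(lysis_hazard(small_env.T, small_env))

    def test_halfway_with_square_slope(self):
        env = Environment(T=0.5, G=2.0)
        assert lysis_hazard(0.25, env) == pytest.approx(0.25)

    def test_nondecreasing_and_positive(self, small_env):
        rhos = np.linspace(1e-6, small_env.T - 1e-6, 50)
        vals = [lysis_hazard(r, small_env) for r in rhos]
        assert all(v > 0 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_domain_checked(self, small_env):
        with pytest.raises(DomainError):
            lysis_hazard(-0.1, small_env)


class TestStep:
    def test_nutrient_depletion_single_class(self, small_env):
        env = small_env.replace(psi0=0.0)
        state = initial_state(env, total=2.0)
        state.psi = 0.0
        dt = 0.01
        new = step(state, env, Strategy(0, 0), dt)
        expected = (state.phi + (env.phi0 - state.phi) * env.B * dt
                    - env.C * state.phi * env.p0 * 2.0 * dt)
        assert new.phi == pytest.approx(expected, rel=1e-12)

    def test_pcd_removes_without_release(self, small_env):
        env = small_env
        strat = Strategy(a=1.0, r=0.0)  # PCD at the first virion
        state = initial_state(env, total=1.0)
        state.n[0, 5] = 0.5  # infected cells above the PCD threshold
        psi_before = state.psi
        new = step(state, env, strat, 0.005)
        assert new.n[:, 2:].sum() == 0.0
        # removal releases nothing (psi changes only via dilution/infection)
        assert new.psi <= psi_before

    def test_division_arrested_with_virus(self, small_env):
        env = small_env.replace(psi0=0.0)
        state = initial_state(env, total=0.0)
        state.psi = 0.0
        state.n[env.p0 - 1, 1] = 1.0  # top size class, one virion
        new = step(state, env, Strategy(0, 0), 0.005)
        assert new.n[0, 0] == 0.0  # no newborns appear

    def test_division_produces_two_newborns(self, small_env):
        env = small_env.replace(psi0=0.0, B=0.05)
        state = initial_state(env, total=0.0)
        state.psi = 0.0
        state.n[env.p0 - 1, 0] = 1.0
        dt = 0.005
        new = step(state, env, Strategy(0, 0), dt)
        flux = env.A * state.phi * env.p_max * 1.0 * dt
        # within-step dilution shaves O(B*dt) off the newborn cohort
        assert new.n[0, 0] == pytest.approx(2 * flux, rel=1e-3)

    def test_step_size_bound_enforced(self, small_env):
        state = initial_state(small_env)
        with pytest.raises(StepSizeError):
            step(state, small_env, Strategy(0, 0), 1.0)

    def test_virion_bookkeeping_closed(self):
        # closed culture (B=0), no replication (F=0): free + intracellular
        # virions change only through immune destruction and PCD removal
        env = Environment(p0=4, Q=30, B=0.0, C=0.02, E=0.5, F=0.0, G=2.0,
                          T=0.9, phi0=1.0, psi0=0.0)

        def virions(s):
            q = np.arange(env.Q + 1)
            return s.psi + (s.n * q).sum()

        state = initial_state(env, total=1.0)
        state.psi = 0.5
        state.n[1, 3] = 0.2
        # ingestion and lysis both conserve the free+intracellular sum
        cur = state
        for _ in range(20):
            cur = step(cur, env, Strategy(a=0.0, r=0.0), 0.002)
        assert virions(cur) == pytest.approx(virions(state), rel=1e-9)
        # immune clearance strictly destroys virions
        cleared = step(cur, env, Strategy(a=0.0, r=0.3), 0.002)
        assert virions(cleared) < virions(cur)
        # PCD (a=1: any virion triggers) silently destroys the entire
        # intracellular load, including virions ingested within the step
        q = np.arange(env.Q + 1)
        intracellular_before = (cur.n * q).sum()
        after = step(cur, env, Strategy(a=1.0, r=0.0), 0.002)
        assert (after.n * q).sum() == 0.0
        assert virions(after) <= virions(cur) - intracellular_before + 1e-12

    def test_nonnegative_and_phi_bounded(self, small_env):
        state = initial_state(small_env)
        for _ in range(200):
            state = step(state, small_env, Strategy(a=0.6, r=0.1), 0.004)
        assert (state.n >= 0).all()
        assert 0 <= state.phi <= small_env.phi0 + 1e-12
        assert state.psi >= 0


class TestRunToEquilibrium:
    def test_division_flux_balances_dilution(self, small_env):
        # virus-free equilibrium: per-capita division rate equals B
        env = small_env.replace(psi0=0.0)
        summary = run_to_equilibrium(env, Strategy(0, 0))
        assert summary.converged and summary.fitness > 0
        st = summary.final_state
        division_rate = env.A * st.phi * env.p_max * st.n[-1, 0]
        assert division_rate / st.n.sum() == pytest.approx(env.B, rel=1e-2)

    def test_full_immunity_investment_goes_extinct(self, small_env):
        summary = run_to_equilibrium(small_env, Strategy(a=0.0, r=small_env.E))
        assert summary.fitness == 0.0 and summary.extinct

    def test_fixed_point_stable_under_longer_runs(self, small_env):
        env = small_env.replace(psi0=0.0)
        s1 = run_to_equilibrium(env, Strategy(0, 0), max_generations=300)
        s2 = run_to_equilibrium(env, Strategy(0, 0), max_generations=600)
        assert s2.fitness == pytest.approx(s1.fitness, rel=1e-3)

    def test_dt_halving_consistency(self, reference_env):
        s1 = run_to_equilibrium(reference_env, Strategy(a=0.6, r=0.1))
        s2 = run_to_equilibrium(reference_env, Strategy(a=0.6, r=0.1),
                                dt_scale=0.5)
        assert s2.fitness == pytest.approx(s1.fitness, rel=0.01)

    def test_monotone_harm_in_viral_pressure(self, small_env):
        fits = [
            run_to_equilibrium(small_env.replace(psi0=v), Strategy(0, 0)).fitness
            for v in (0.0, 0.3, 1.0, 3.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(fits, fits[1:]))

    def test_full_pcd_blocks_all_transmission(self, small_env):
        # a=1: PCD fires on the first virion; no lysis ever releases virus,
        # so the free-virus pool converges to the influent level
        env = small_env.replace(psi0=0.2)
        summary = run_to_equilibrium(env, Strategy(a=1.0, r=0.0))
        st = summary.final_state
        assert st.n[:, 2:].sum() == pytest.approx(0.0, abs=1e-12)
        assert st.psi <= env.psi0 + 1e-9

    def test_invalid_arguments(self, small_env):
        with pytest.raises(ValueError):
            run_to_equilibrium(small_env, Strategy(0, 0), max_generations=0)


class TestBurstDistribution:
    def test_point_mass_single_class(self, small_env):
        state = initial_state(small_env, total=0.0)
        state.n[0, 7] = 2.0
        dist = burst_size_distribution(state, small_env)
        assert not dist.empty
        assert dist.pmf[6] == pytest.approx(1.0)  # index 6 <-> q = 7

    def test_virus_free_state_is_empty(self, small_env):
        state = initial_state(small_env, total=5.0)
        dist = burst_size_distribution(state, small_env)
        assert dist.empty

    def test_bimodal_under_low_slope_fast_replication(self):
        # most cells sit at low load (division-arrested tail) while the
        # autocatalytic replication piles a second peak near the lethal
        # concentration -> two-peaked burst distribution
        env = Environment(p0=6, Q=200, B=0.15, C=0.01, E=0.5, F=0.6, G=1.0,
                          T=0.6, phi0=1.0, psi0=0.05)
        summary = run_to_equilibrium(env, Strategy(a=0.0, r=0.1),
                                     max_generations=300)
        assert summary.fitness > 0
        dist = burst_size_distribution(summary.final_state, env,
                                       dt=summary.dt_last)
        assert not dist.empty
        assert dist.mode_count(rel_floor=1e-4) >= 2
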