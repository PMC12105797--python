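"""Treatment-response primitives and the forward simulator."""

import math

import numpy as np
import pytest

import gliosel as g
from gliosel.forward import stability_bound
from gliosel.grid import Grid


class TestOerMap:
    def test_max_voxel_gets_one(self):
        er = np.array([1.0, 1.4, 2.0, 1.2])
        oer = g.oer_map(er)
        assert oer[2] == pytest.approx(1.0)
        assert np.all(oer >= 1.0)

    def test_constant_field_all_ones(self):
        assert np.allclose(g.oer_map(np.full((4, 4, 3), 1.3)), 1.0)

    def test_arithmetic(self):
        oer = g.oer_map(np.array([2.0, 1.2]))
        assert oer[1] == pytest.approx(1.8)

    def test_mask_restricts_max(self):
        er = np.array([5.0, 2.0, 1.0])
        oer = g.oer_map(er, brain_mask=np.array([False, True, True]))
        assert oer[1] == pytest.approx(1.0)  # in-mask maximum

    def test_empty_mask_and_bad_values(self):
        with pytest.raises(ValueError):
            g.oer_map(np.ones(3), brain_mask=np.zeros(3, bool))
        with pytest.raises(ValueError):
            g.oer_map(np.array([1.0, -0.5]))


class TestSurvivingFractions:
    def test_lq_zero_dose(self):
        assert g.surviving_fraction_lq(0.1, 0.0, 10.0) == pytest.approx(1.0)

    def test_lq_closed_form(self):
        # alpha=0.1/Gy, D=2 Gy, alpha/beta=10 Gy -> exp(-0.24)
        assert g.surviving_fraction_lq(0.1, 2.0, 10.0) == pytest.approx(
            math.exp(-0.24), rel=1e-12
        )

    def test_ct_convention_drops_quadratic(self):
        assert g.surviving_fraction_lq(0.05, 2.0, None) == pytest.approx(
            math.exp(-0.1), rel=1e-12
        )

    @pytest.mark.parametrize("alpha,dose", [(-0.1, 1.0), (0.1, -1.0)])
    def test_negative_inputs_rejected(self, alpha, dose):
        with pytest.raises(ValueError):
            g.surviving_fraction_lq(alpha, dose, 10.0)

    def test_monotone_in_dose_and_alpha(self):
        doses = np.linspace(0, 10, 25)
        sf = g.surviving_fraction_lq(0.1, doses, 10.0)
        assert np.all(np.diff(sf) < 0)
        alphas = np.linspace(0.0, 0.5, 25)
        sf = g.surviving_fraction_lq(alphas, 2.0, 10.0)
        assert np.all(np.diff(sf) < 0)

    def test_oer_reduces_to_lq_at_one(self):
        assert g.surviving_fraction_oer(0.1, 2.0, 10.0, 1.0) == pytest.approx(
            g.surviving_fraction_lq(0.1, 2.0, 10.0), rel=1e-14
        )

    def test_oer_closed_form(self):
        # effective dose 1 Gy: exp(-0.1*(1 + 0.1)) = exp(-0.11)
        assert g.surviving_fraction_oer(0.1, 2.0, 10.0, 2.0) == pytest.approx(
            math.exp(-0.11), rel=1e-12
        )

    def test_oer_limit_no_effect(self):
        assert g.surviving_fraction_oer(0.1, 2.0, 10.0, 1e12) == pytest.approx(1.0)

    def test_oer_below_one_rejected(self):
        with pytest.raises(ValueError):
            g.surviving_fraction_oer(0.1, 2.0, 10.0, 0.9)

    def test_density_endpoints_and_midpoint(self):
        c = g.DEFAULT_CONSTANTS
        assert g.surviving_fraction_density(0.6, 0.0, 0.0, c) == pytest.approx(1.0)
        assert g.surviving_fraction_density(
            0.6, c.theta_E, c.theta_N, c
        ) == pytest.approx(0.6)
        half = 0.5 * (c.theta_E + c.theta_N)
        assert g.surviving_fraction_density(0.6, half, 0.0, c) == pytest.approx(0.8)

    def test_density_validates_capacity(self):
        with pytest.raises(ValueError, match="capacit"):
            g.surviving_fraction_density(0.5, 1.5, 0.0)


class TestTreatmentEventAndProliferation:
    def test_identity_event(self):
        st = g.TumourState(N_E=np.full(4, 0.5), N_N=np.full(4, 0.1), day=0)
        out = g.apply_treatment_event(st, np.ones(4), np.ones(4))
        assert np.array_equal(out.N_E, st.N_E)

    def test_product_reduction(self):
        st = g.TumourState(N_E=np.array([0.5]), N_N=np.array([0.0]), day=0)
        out = g.apply_treatment_event(st, np.array([0.5]), np.array([0.8]))
        assert out.N_E[0] == pytest.approx(0.2)

    def test_bad_sf_rejected(self):
        st = g.TumourState(N_E=np.array([0.5]), N_N=np.array([0.0]), day=0)
        with pytest.raises(ValueError):
            g.apply_treatment_event(st, np.array([1.2]), np.array([1.0]))
        with pytest.raises(ValueError):
            g.apply_treatment_event(st, np.array([0.5]), np.array([0.0]))

    def test_effective_proliferation(self):
        assert g.effective_proliferation(0.1, 0.95, 0) == pytest.approx(0.1)
        assert g.effective_proliferation(0.1, 1.0, 17) == pytest.approx(0.1)
        assert g.effective_proliferation(1.0, 0.95, 10) == pytest.approx(
            0.95 ** 10, rel=1e-12
        )
        with pytest.raises(ValueError):
            g.effective_proliferation(0.1, 0.95, -1)


class TestGrowthStep:
    def test_zero_state_absorbing(self, anatomy, growth_params):
        grid = anatomy.grid
        zero = g.TumourState(N_E=np.zeros(grid.dims), N_N=np.zeros(grid.dims), day=0)
        d = grid.unflatten(np.full(grid.n_inside, 0.1))
        out = g.growth_step(zero, d, d, 0.05, 0.05, growth_params,
                            g.DEFAULT_CONSTANTS, 0.1, grid)
        assert np.all(out.N_E == 0) and np.all(out.N_N == 0)

    def test_carrying_capacity_fixed_point(self, anatomy):
        grid = anatomy.grid
        c = g.DEFAULT_CONSTANTS
        p = g.ParameterSet(kpE=0.08, beta_NE=0.0, beta_EN=0.0)
        full = g.TumourState(
            N_E=np.where(grid.brain_mask, c.theta_E, 0.0),
            N_N=np.zeros(grid.dims), day=0,
        )
        zero_d = np.zeros(grid.dims)
        out = g.growth_step(full, zero_d, zero_d, p.kpE, 0.0, p, c, 0.1, grid)
        assert np.allclose(out.N_E, full.N_E)

    def test_three_voxel_stencil_hand_computed(self):
        """1-D profile: update equals a hand-evaluated central difference."""
        grid = Grid(dims=(3, 1, 1), spacing=(1.0, 1.0, 1.0))
        c = g.DEFAULT_CONSTANTS
        p = g.ParameterSet(kpE=0.1)
        n = np.array([0.1, 0.5, 0.2]).reshape(3, 1, 1)
        d_val, dt = 0.3, 0.01
        d = np.full((3, 1, 1), d_val)
        out = g.growth_step(
            g.TumourState(N_E=n, N_N=np.zeros_like(n), day=0),
            d, d, p.kpE, 0.0, p, c, dt, grid,
        )
        lap = d_val * np.array(
            [(0.5 - 0.1), (0.1 - 0.5) + (0.2 - 0.5), (0.5 - 0.2)]
        )  # zero-flux ends
        react = 0.1 * n.ravel() * (1 - n.ravel() / c.theta_E)
        expected = n.ravel() + dt * (lap + react)
        assert np.max(np.abs(out.N_E.ravel() - expected)) < 1e-12

    def test_stability_bound_enforced(self, anatomy, growth_params):
        grid = anatomy.grid
        d = np.full(grid.dims, 5.0)  # enormous diffusivity
        st = anatomy.initial_state
        with pytest.raises(ValueError, match="stability"):
            g.growth_step(st, d, d, 0.0, 0.0, growth_params,
                          g.DEFAULT_CONSTANTS, 0.1, grid)
        assert stability_bound(0.5, (0.5, 0.5, 2.0)) == pytest.approx(
            0.9 / (2 * 0.5 * (4 + 4 + 0.25))
        )


class TestSimulate:
    def test_observation_days_returned_in_order(self, anatomy, schedule, workspace,
                                                growth_params):
        days = (0, 7, 14, 21, 67)
        out = g.simulate(g.get_variant("M11"), growth_params, anatomy, schedule,
                         days, workspace=workspace)
        assert tuple(int(s.day) for s in out.states) == days

    def test_first_observation_must_match_initial_day(self, anatomy, schedule,
                                                      workspace, growth_params):
        with pytest.raises(ValueError, match="first observation"):
            g.simulate(g.get_variant("M11"), growth_params, anatomy, schedule,
                       (7, 14), workspace=workspace)

    def test_mass_conserved_without_growth_or_treatment(self, anatomy, schedule,
                                                        workspace):
        """Pure zero-flux diffusion conserves total density to round-off."""
        p = g.ParameterSet(kpE=0.0, kpN=0.0, D_w=0.2, D_g=0.1, f_NE=1.0,
                           lambda1=0.3)
        out = g.simulate(g.get_variant("M11"), p, anatomy, schedule,
                         (0, 21), workspace=workspace)
        m0 = out.states[0].total().sum()
        m1 = out.states[1].total().sum()
        assert abs(m1 - m0) / m0 < 1e-10

    def test_treatment_free_m1_equals_m11(self, anatomy, schedule, workspace,
                                          growth_params):
        """Nesting: M1 with inert sensitivities reproduces M11 voxelwise."""
        import dataclasses

        p = dataclasses.replace(growth_params, alpha_RT=0.0, alpha_CT=0.0,
                                alpha_RT_prolif=0.0, alpha_beta=10.0)
        days = (0, 7, 21)
        out1 = g.simulate(g.get_variant("M1"), p, anatomy, schedule, days,
                          workspace=workspace)
        out11 = g.simulate(g.get_variant("M11"), p, anatomy, schedule, days,
                           workspace=workspace)
        for s1, s11 in zip(out1.states, out11.states):
            assert np.array_equal(s1.N_E, s11.N_E)
            assert np.array_equal(s1.N_N, s11.N_N)

    def test_higher_rt_sensitivity_never_increases_density(self, anatomy, schedule,
                                                           workspace, growth_params):
        import dataclasses

        lo = dataclasses.replace(growth_params, alpha_RT=0.05, alpha_CT=0.05,
                                 alpha_RT_prolif=0.01, alpha_beta=10.0)
        hi = dataclasses.replace(lo, alpha_RT=0.15)
        days = (0, 21)
        out_lo = g.simulate(g.get_variant("M1"), lo, anatomy, schedule, days,
                            workspace=workspace)
        out_hi = g.simulate(g.get_variant("M1"), hi, anatomy, schedule, days,
                            workspace=workspace)
        assert np.all(out_hi.states[1].N_E <= out_lo.states[1].N_E + 1e-12)
        assert np.all(out_hi.states[1].N_N <= out_lo.states[1].N_N + 1e-12)

    def test_constant_er_reduces_vasculature_to_uniform(self, anatomy, schedule,
                                                        growth_params):
        """With a flat ER map, OER = 1 everywhere and M3/M5 collapse to M1."""
        import dataclasses

        flat = dataclasses.replace(anatomy, er_map=np.ones(anatomy.grid.dims))
        ws = g.SimulationWorkspace(flat)
        p = dataclasses.replace(growth_params, alpha_RT=0.1, alpha_CT=0.1,
                                alpha_RT_prolif=0.01, alpha_beta=10.0)
        days = (0, 14, 21)
        ref = g.simulate(g.get_variant("M1"), p, flat, schedule, days, workspace=ws)
        for vid in ("M3", "M5"):
            out = g.simulate(g.get_variant(vid), p, flat, schedule, days,
                             workspace=ws)
            for s_ref, s in zip(ref.states, out.states):
                assert np.allclose(s.N_E, s_ref.N_E, atol=1e-14)
                assert np.allclose(s.N_N, s_ref.N_N, atol=1e-14)

    def test_density_bounds_hold_everywhere(self, anatomy, schedule, workspace, rng):
        bounds = g.ParameterBounds()
        c = g.DEFAULT_CONSTANTS
        for vid in ("M1", "M7", "M9"):
            p = g.sample_parameters(vid, bounds, rng)
            out = g.simulate(g.get_variant(vid), p, anatomy, schedule,
                             (0, 21, 67), workspace=workspace)
            for st in out.states:
                assert np.all(st.N_E >= 0) and np.all(st.N_E <= c.theta_E)
                assert np.all(st.N_N >= 0) and np.all(st.N_N <= c.theta_N)
                assert np.all(st.N_E[~anatomy.grid.brain_mask] == 0)

    def test_halved_dt_changes_fields_little(self, anatomy, schedule, growth_params):
        """First-order consistency: halving dt moves day-21 fields only slightly."""
        import dataclasses

        ws = g.SimulationWorkspace(anatomy)
        p = dataclasses.replace(growth_params, alpha_RT=0.08, alpha_CT=0.1,
                                alpha_RT_prolif=0.01, alpha_beta=10.0)
        coarse = g.simulate(g.get_variant("M1"), p, anatomy, schedule, (0, 21),
                            config=g.SolverConfig(dt_max=0.1), workspace=ws)
        fine = g.simulate(g.get_variant("M1"), p, anatomy, schedule, (0, 21),
                          config=g.SolverConfig(dt_max=0.05), workspace=ws)
        diff = np.max(np.abs(coarse.states[1].N_E - fine.states[1].N_E))
        assert diff < 5e-3
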