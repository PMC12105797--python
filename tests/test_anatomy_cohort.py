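"""Synthetic anatomy, schedules, parameter sampling and observation noise."""

import numpy as np
import pytest

import gliosel as g
from gliosel.grid import GREY, WHITE


class TestMakeAnatomy:
    def test_deterministic_for_seed(self):
        a, b = g.make_anatomy(11), g.make_anatomy(11)
        assert np.array_equal(a.grid.brain_mask, b.grid.brain_mask)
        assert np.array_equal(a.initial_state.N_E, b.initial_state.N_E)
        assert np.array_equal(a.er_map, b.er_map)

    def test_distinct_seeds_differ(self):
        a, b = g.make_anatomy(1), g.make_anatomy(2)
        ea = a.initial_state.N_E > 0
        eb = b.initial_state.N_E > 0
        jaccard = (ea & eb).sum() / max((ea | eb).sum(), 1)
        assert jaccard < 1.0

    def test_white_and_grey_partition_mask(self):
        a = g.make_anatomy(7)
        inside = a.grid.tissue_labels != 0
        assert np.array_equal(inside, a.grid.brain_mask)
        labels = a.grid.tissue_labels[a.grid.brain_mask]
        assert set(np.unique(labels)) == {WHITE, GREY}

    def test_initial_condition_structure(self):
        a = g.make_anatomy(5)
        n_n = a.initial_state.N_N
        rim = n_n > 0
        assert np.allclose(n_n[rim], g.DEFAULT_CONSTANTS.theta_N)
        n_e = a.initial_state.N_E
        assert n_e.min() >= 0 and n_e.max() <= 1
        assert not np.any(rim & (n_e > 0))  # rim surrounds, not overlaps
        assert np.all(n_e[~a.grid.brain_mask] == 0)

    def test_target_volumes_nested(self):
        a = g.make_anatomy(9)
        assert np.all(~a.gtv_mask | a.ctv_mask)          # gtv within ctv
        assert np.all(~a.ctv_mask | a.grid.brain_mask)   # ctv within brain

    def test_small_dims_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            g.make_anatomy(1, dims=(8, 8, 3))


class TestAdcMapping:
    def test_endpoints(self):
        assert g.adc_to_density(3.0e-3) == pytest.approx(0.0)
        assert g.adc_to_density(0.5e-3) == pytest.approx(1.0)

    def test_linear_midpoint(self):
        assert g.adc_to_density(1.75e-3, adc_min=0.5e-3) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.adc_to_density(3.5e-3)
        with pytest.raises(ValueError):
            g.adc_to_density(0.1e-3)

    def test_round_trip_through_pseudo_adc(self):
        a = g.make_anatomy(4)
        inside = a.grid.brain_mask
        recovered = g.adc_to_density(a.adc_map[inside])
        assert np.allclose(recovered, a.initial_state.N_E[inside], atol=1e-12)


class TestSchedule:
    def test_default_prescription(self, anatomy, schedule):
        assert len(schedule) == 30
        days = [ev.day for ev in schedule]
        assert days[0] == 0 and days[-1] == 39
        assert all(d % 7 < 5 for d in days)  # weekdays only
        assert [ev.fraction_index for ev in schedule] == list(range(1, 31))
        assert all(ev.has_ct for ev in schedule)

    def test_cumulative_doses(self, anatomy, schedule):
        total = sum(ev.dose_map for ev in schedule)
        assert np.allclose(total[anatomy.gtv_mask], 60.0)
        ring = anatomy.ctv_mask & ~anatomy.gtv_mask
        if ring.any():  # penumbra: between 0 and the GTV prescription
            assert total[ring].max() <= 60.0 + 1e-9
            assert total[ring].min() >= 0.0
        assert np.all(total[~anatomy.grid.brain_mask] == 0)

    def test_sharp_two_level_map_without_penumbra(self, anatomy):
        events = g.make_schedule(anatomy, penumbra_sigma_mm=0.0)
        total = sum(ev.dose_map for ev in events)
        assert np.allclose(total[anatomy.gtv_mask], 60.0)
        ring = anatomy.ctv_mask & ~anatomy.gtv_mask
        if ring.any():
            assert np.allclose(total[ring], 50.0)
        outside_ctv = anatomy.grid.brain_mask & ~anatomy.ctv_mask
        assert np.all(total[outside_ctv] == 0)

    def test_penumbra_gives_dose_continuum(self, anatomy, schedule):
        dose = schedule[0].dose_map
        inside = dose[anatomy.grid.brain_mask]
        assert len(np.unique(np.round(inside, 6))) > 10

    def test_bad_fraction_count(self, anatomy):
        with pytest.raises(ValueError):
            g.make_schedule(anatomy, n_fractions=0)


class TestSampleParameters:
    def test_within_bounds_and_fixed_rules(self, bounds, rng):
        for vid, variant in g.VARIANTS.items():
            p = g.sample_parameters(variant, bounds, rng)
            assert bounds.contains(p, variant.free_params)
            if vid in ("M2", "M4", "M8"):
                assert p.alpha_CT == 1.0
        p11 = g.sample_parameters("M11", bounds, rng)
        assert len(g.get_variant("M11").free_params) == 8
        assert p11.alpha_RT == 0.0 and p11.alpha_CT == 0.0

    def test_distinct_draws(self, bounds):
        a = g.sample_parameters("M1", bounds, np.random.default_rng(1))
        b = g.sample_parameters("M1", bounds, np.random.default_rng(2))
        assert a != b


class TestAddNoise:
    def _uniform_state(self, grid, value_e=0.5, value_n=0.08):
        return g.TumourState(
            N_E=np.where(grid.brain_mask, value_e, 0.0),
            N_N=np.where(grid.brain_mask, value_n, 0.0),
            day=0.0,
        )

    def test_zero_level_identity(self, anatomy, rng):
        st = self._uniform_state(anatomy.grid)
        (noisy,) = g.add_noise([st], 0.0, rng, anatomy.grid)
        assert np.array_equal(noisy.N_E, st.N_E)

    def test_empirical_sd_matches_level(self):
        """Far from the clip boundaries the injected SD is the nominal level."""
        grid = g.Grid(dims=(40, 40, 3))
        st = g.TumourState(
            N_E=np.full(grid.dims, 0.5), N_N=np.zeros(grid.dims), day=0.0
        )
        (noisy,) = g.add_noise([st], 0.05, np.random.default_rng(0), grid)
        sd = (noisy.N_E - st.N_E)[grid.brain_mask].std()
        assert sd == pytest.approx(0.05, rel=0.05)

    def test_default_noise_is_zero_mean(self, anatomy):
        st = anatomy.initial_state
        mask = anatomy.grid.brain_mask
        (noisy,) = g.add_noise([st], 0.15, np.random.default_rng(3), anatomy.grid)
        delta = (noisy.N_E - st.N_E)[mask]
        assert np.any(noisy.N_E[mask] < 0)  # untruncated floor
        assert abs(delta.mean()) < 3 * 0.15 / np.sqrt(mask.sum())

    def test_optional_truncation_to_admissible_range(self, anatomy):
        st = anatomy.initial_state
        c = g.DEFAULT_CONSTANTS
        (noisy,) = g.add_noise([st], 0.15, np.random.default_rng(3), anatomy.grid,
                               truncate=True)
        assert noisy.N_E.min() >= 0 and noisy.N_E.max() <= c.theta_E
        assert noisy.N_N.min() >= 0 and noisy.N_N.max() <= c.theta_N + 1e-15

    def test_negative_level_rejected(self, anatomy, rng):
        with pytest.raises(ValueError):
            g.add_noise([anatomy.initial_state], -0.1, rng, anatomy.grid)

    def test_unusual_level_warns(self, anatomy, rng):
        with pytest.warns(UserWarning, match="unusual"):
            g.add_noise([anatomy.initial_state], 0.3, rng, anatomy.grid)


class TestGenerateCohort:
    def test_counts_and_reproducibility(self):
        kwargs = dict(
            n_patients=2, variants=["M11", "M7"], noise_levels=(0.05,),
            master_seed=42,
        )
        patients, manifest = g.generate_cohort(**kwargs)
        assert len(patients) == 4          # patients x variants
        assert len(manifest) == 4
        for p in patients:
            assert len(p.truth.states) == 5
            assert set(p.observations) == {0.05}
        patients2, manifest2 = g.generate_cohort(**kwargs)
        assert manifest.equals(manifest2)
        for a, b in zip(patients, patients2):
            assert np.array_equal(a.truth.states[-1].N_E, b.truth.states[-1].N_E)
            assert np.array_equal(
                a.observations[0.05][0].N_E, b.observations[0.05][0].N_E
            )

    def test_invalid_patient_count(self):
        with pytest.raises(ValueError):
            g.generate_cohort(0)
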