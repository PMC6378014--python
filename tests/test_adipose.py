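"""Adipocyte population dynamics: swelling/adipogenesis probabilities, the
volume floor, initialisation and recruitment."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from adipoflame import (
    AdipocytePopulation,
    GrowthParams,
    adipogenesis_probability,
    critical_volume,
    init_population,
    recruit_adipocytes,
    sphere_volume,
    supercritical_fraction,
    swelling_factor,
    swelling_probability,
    update_volumes,
)
from adipoflame.errors import InvalidInputError

V_C = critical_volume("male")


def make_population(volumes):
    return AdipocytePopulation(np.asarray(volumes, dtype=float), v0=8.181e-6)


def male_params(**overrides):
    return GrowthParams.for_gender("male", **overrides)


class TestSwelling:
    def test_swelling_factor_anchor_points(self):
        assert swelling_factor(V_C, V_C) == 0.0
        assert swelling_factor(2 * V_C, V_C) == -1.0
        # Diaz initial cell: 1 - (96.9649/120)^3
        v_init = sphere_volume(96.9648653)
        assert swelling_factor(v_init, V_C) == pytest.approx(0.4724, abs=1e-3)

    def test_probability_values(self):
        assert swelling_probability(0.0) == pytest.approx(0.5 * (1 + math.tanh(2)), rel=1e-12)
        assert swelling_probability(0.0) == pytest.approx(0.98201, abs=1e-5)
        assert swelling_probability(-1.0) == pytest.approx(0.01799, abs=1e-5)
        assert swelling_probability(0.7, k1=0.0, k2=0.0) == 0.5

    @given(st.floats(min_value=-50, max_value=50))
    def test_probability_bounds(self, theta):
        p = swelling_probability(theta)
        assert 0.0 <= p <= 1.0  # tanh saturates in float at extreme theta
        if abs(theta) <= 4:
            assert 0.0 < p < 1.0

    def test_strictly_decreasing_in_volume(self):
        v = np.linspace(0.1 * V_C, 3 * V_C, 300)
        p = swelling_probability(swelling_factor(v, V_C))
        assert np.all(np.diff(p) < 0)


class TestAdipogenesis:
    def test_zero_at_zero_fraction(self):
        # exact tanh-oddness identity with the default k6 = -1
        assert adipogenesis_probability(0.0) == 0.0

    def test_printed_anchor_values(self):
        assert adipogenesis_probability(1.0) == pytest.approx(0.88046, abs=1e-5)
        assert adipogenesis_probability(0.2) == pytest.approx(0.5 * math.tanh(1), rel=1e-12)

    def test_clipped_for_non_default_params(self):
        assert adipogenesis_probability(0.0, k5=5, k6=-10) == 0.0

    @given(
        zeta=st.floats(min_value=0, max_value=1),
        k5=st.floats(min_value=0, max_value=20),
        k6=st.floats(min_value=-10, max_value=10),
    )
    def test_bounds(self, zeta, k5, k6):
        p = adipogenesis_probability(zeta, k5, k6)
        assert 0.0 <= p <= 1.0

    def test_non_decreasing_in_zeta(self):
        zeta = np.linspace(0, 1, 100)
        p = adipogenesis_probability(zeta)
        assert np.all(np.diff(p) >= 0)


class TestUpdateVolumes:
    def test_zero_energy_zero_noise_is_identity(self, rng):
        params = male_params(k4=0.0)
        pop = make_population([2e-4, 5e-4, 9e-4])
        new = update_volumes(pop, 0.0, params, 3, rng)
        assert np.array_equal(new.volumes, pop.volumes)

    def test_cell_at_floor_stays_under_starvation(self, rng):
        params = male_params(k4=0.0)
        v0 = params.v0
        pop = make_population([v0, 5e-4])
        for _ in range(50):
            pop = update_volumes(pop, -2000.0, params, 3, rng)
        assert pop.volumes[0] == v0  # floor cell never moves
        assert pop.volumes.min() >= v0

    @given(
        energies=st.lists(
            st.floats(min_value=-5000, max_value=5000), min_size=1, max_size=30
        )
    )
    def test_volume_floor_under_adversarial_energy(self, energies):
        rng = np.random.default_rng(7)
        params = male_params()
        pop = make_population([8.181e-6, 1e-5, 4e-4, 9.5e-4])
        for e in energies:
            pop = update_volumes(pop, e, params, 3, rng)
            assert pop.volumes.min() >= params.v0

    def test_no_passing_cells_means_no_change(self, rng):
        params = male_params(k2=-50.0)  # p_s ~ 0 everywhere
        pop = make_population([4e-4] * 100)
        new = update_volumes(pop, 1506.0, params, 3, rng)
        assert np.array_equal(new.volumes, pop.volumes)

    def test_per_cell_increment_magnitude(self, rng):
        # with all cells passing and no noise, each gains scale*k3*E/steps
        params = male_params(k4=0.0, k2=50.0)
        pop = make_population([4e-4] * 10)
        new = update_volumes(pop, 1506.0, params, 3, rng)
        inc = params.energy_partition_scale * params.k3 * 1506.0 / 3
        assert np.allclose(new.volumes - pop.volumes, inc, rtol=1e-12)

    def test_tissue_partition_conserves_total_influx(self, rng):
        params = male_params(k4=0.0, k2=50.0, partition_mode="tissue")
        pop = make_population([4e-4] * 10)
        new = update_volumes(pop, 900.0, params, 3, rng, sim_volume=1.0)
        expected = params.energy_partition_scale * params.k3 * 300.0 * pop.total_volume
        assert new.total_volume - pop.total_volume == pytest.approx(expected, rel=1e-9)

    def test_total_volume_consistency(self, rng):
        params = male_params()
        pop = make_population(np.full(50, 4e-4))
        pop = update_volumes(pop, 1000.0, params, 3, rng)
        assert pop.total_volume == pytest.approx(float(pop.volumes.sum()), rel=1e-15)


class TestSupercriticalFraction:
    @pytest.mark.parametrize(
        "scales,expected",
        [([0.5, 0.9, 0.8], 0.0), ([1.1, 1.5, 2.0], 1.0), ([0.5, 1.1, 1.2, 0.9], 0.5)],
    )
    def test_counting(self, scales, expected):
        pop = make_population([s * V_C for s in scales])
        assert supercritical_fraction(pop, V_C) == expected


class TestRecruitment:
    def test_zero_probability_is_identity(self, rng):
        pop = make_population([4e-4] * 5)
        new = recruit_adipocytes(pop, 0.0, 1.0, male_params(), rng)
        assert new.n == pop.n

    def test_certain_recruitment_adds_one_cell_per_microliter(self, rng):
        params = male_params()
        pop = make_population([4e-4] * 5)
        new = recruit_adipocytes(pop, 1.0, 1.0, params, rng)
        assert new.n == pop.n + 1
        assert new.volumes[-1] == params.v0
        assert new.total_volume == pytest.approx(pop.total_volume + params.v0)

    def test_expected_recruits_match_bernoulli_mean(self):
        rng = np.random.default_rng(3)
        params = male_params()
        p_a, trials = 0.3, 2000
        added = 0
        pop = make_population([4e-4] * 5)
        for _ in range(trials):
            new = recruit_adipocytes(pop, p_a, 1.0, params, rng)
            added += new.n - pop.n
        assert added / trials == pytest.approx(p_a, abs=0.03)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            recruit_adipocytes(make_population([4e-4]), 1.5, 1.0, male_params(), rng)


class TestInitPopulation:
    def test_diaz_population_size_and_diameter(self, rng, diaz_profile):
        params = male_params()
        pop = init_population(diaz_profile, params, 1.0, rng)
        assert 2050 <= pop.n <= 2140  # 1 μL / volume(96.96 μm) ≈ 2095
        from adipoflame import sphere_diameter

        mean_d = np.mean([sphere_diameter(v) for v in pop.volumes])
        assert mean_d == pytest.approx(96.96, rel=0.01)
        assert pop.volumes.min() >= params.v0

    def test_population_scales_linearly_with_volume(self, rng, diaz_profile):
        params = male_params()
        n1 = init_population(diaz_profile, params, 1.0, rng).n
        n2 = init_population(diaz_profile, params, 2.0, rng).n
        assert abs(n2 - 2 * n1) <= 1

    def test_small_population_warns(self, rng, diaz_profile):
        with pytest.warns(UserWarning, match="too small"):
            init_population(diaz_profile, male_params(), 0.003, rng)


class TestSaturation:
    def test_mean_volume_stays_below_twice_critical(self):
        """Sustained strong overfeeding cannot push the population mean past
        2*v_c: the swelling probability collapses there."""
        from adipoflame import DietProtocol, SimulationConfig, SubjectProfile, run

        cfg = SimulationConfig(
            subject=SubjectProfile(60.0, 1.70, 35, "male"),
            protocol=DietProtocol(2000.0, 730),
            replicates=1,
            base_seed=99,
        )
        traj = run(cfg)
        assert (traj.frame["mean_volume_ul"] < 2 * V_C).all()
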