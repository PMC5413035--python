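"""Individual-based gene-flow simulator: initialisation, annual cycle,
dispersal and viability kernels, experiment bookkeeping."""

import numpy as np
import pytest

from resispread.core import CapacityError, ConfigurationError, RasterGrid
from resispread.simulate import (
    SimConfig,
    SimState,
    bracket_dispersal_thresholds,
    default_mortality,
    dispersal_weights,
    init_novel_allele,
    init_preexisting_allele,
    init_state,
    place_individuals,
    place_individuals_n,
    run_experiment,
    stable_age_distribution,
    step_year,
    viability_weights,
)


def flat_cost(m, value=100.0):
    c = np.full((m, m), float(value))
    np.fill_diagonal(c, 0.0)
    return c


def line_state(m, n_occupied=None, seed=0, age=2):
    """Manually built state on a line of locations (first n occupied)."""
    rng = np.random.default_rng(seed)
    locs = np.column_stack([np.arange(m, dtype=float), np.zeros(m)])
    occupied = np.zeros(m, dtype=bool)
    occupied[: (m if n_occupied is None else n_occupied)] = True
    return SimState(
        locations=locs,
        occupied=occupied,
        sex=rng.integers(0, 2, m).astype(np.int8),
        age=np.full(m, age, dtype=np.int16),
        sel=np.zeros((m, 2), dtype=np.int8),
    )


def basic_config(**kw):
    kw.setdefault("d_max", 1e12)
    kw.setdefault("d_floor", 1.0)
    return SimConfig(**kw)


class TestPlacement:
    def test_density_arithmetic(self):
        # 500 habitat cells of 1 km^2 at 0.2 / km^2 -> 100 individuals
        mask = RasterGrid(np.ones((20, 25)), cell_size=1000.0)
        coords = place_individuals(mask, 0.2, seed=0)
        assert len(coords) == 100

    def test_zero_density_gives_empty_population(self):
        mask = RasterGrid(np.ones((10, 10)), cell_size=1000.0)
        assert len(place_individuals(mask, 0.0, seed=0)) == 0

    def test_all_locations_on_habitat_cells(self):
        rng = np.random.default_rng(5)
        values = (rng.random((15, 15)) < 0.4).astype(float)
        mask = RasterGrid(values, cell_size=100.0)
        coords = place_individuals_n(mask, 10, seed=1)
        for x, y in coords:
            r, c = mask.point_to_cell(x, y)
            assert values[r, c] == 1.0

    def test_capacity_error(self):
        mask = RasterGrid(np.ones((3, 3)), cell_size=100.0)
        with pytest.raises(CapacityError):
            place_individuals_n(mask, 10, seed=0)

    def test_initial_ages_follow_stable_distribution(self):
        cfg = basic_config()
        state = init_state(np.zeros((20000, 2)), cfg, seed=3)
        pi = stable_age_distribution(cfg.mortality)
        observed = np.bincount(state.age, minlength=17) / 20000
        assert np.max(np.abs(observed - pi)) < 0.02


class TestInitNovel:
    def make(self, n=1000):
        state = line_state(n)
        cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float) * 10
        return state, cost

    def test_regional_frequency_is_one_percent_exactly(self):
        state, cost = self.make(1000)
        init_novel_allele(state, cost, 0.02, seed=4)
        assert state.sel.sum() == 20
        assert state.sel.sum() / (2 * 1000) == pytest.approx(0.01)

    def test_cluster_genotype_counts_are_hwe_at_half(self):
        state, cost = self.make(1000)
        init_novel_allele(state, cost, 0.02, seed=4)
        counts = state.sel.sum(axis=1)
        assert np.sum(counts == 2) == 5
        assert np.sum(counts == 1) == 10
        carriers = np.flatnonzero(counts > 0)
        assert len(carriers) <= 20

    def test_cluster_is_cost_contiguous_and_rest_aa(self):
        state, cost = self.make(500)
        init_novel_allele(state, cost, 0.02, seed=1)
        carriers = np.flatnonzero(state.sel.sum(axis=1) > 0)
        # seed individual sits nearest the centroid of the line (index ~250)
        assert np.all(np.abs(carriers - 249.5) < 20)
        non_cluster = np.setdiff1d(np.arange(500), carriers)
        assert np.all(state.sel[non_cluster] == 0)

    def test_cluster_larger_than_population_rejected(self):
        state, cost = self.make(10)
        with pytest.raises(ConfigurationError):
            init_novel_allele(state, cost, 2.0, seed=0)


class TestInitPreexisting:
    def test_exact_copy_count(self):
        state = line_state(1000)
        init_preexisting_allele(state, 0.05, seed=9)
        assert state.sel.sum() == 100
        assert state.sel.sum() / 2000 == pytest.approx(0.05)

    def test_p0_zero_gives_all_aa(self):
        state = line_state(100)
        init_preexisting_allele(state, 0.0, seed=0)
        assert state.sel.sum() == 0

    def test_heterozygote_count_matches_permutation_expectation(self):
        """Random placement of 2Np0 copies over 2N slots: the expected
        heterozygote count follows the without-replacement two-slot law."""
        n, p0 = 1000, 0.05
        n_a = round(2 * n * p0)
        expected = n * 2 * n_a * (2 * n - n_a) / (2 * n * (2 * n - 1))
        hets = []
        for seed in range(50):
            state = line_state(n)
            init_preexisting_allele(state, p0, seed=seed)
            hets.append(int(np.sum(state.sel.sum(axis=1) == 1)))
        hets = np.asarray(hets, dtype=float)
        se = hets.std(ddof=1) / np.sqrt(len(hets))
        assert abs(hets.mean() - expected) < 3 * se + 1e-9


class TestKernels:
    def test_inverse_square_normalisation(self):
        w = dispersal_weights(np.array([10.0, 20.0]), d_max=100, d_floor=1)
        np.testing.assert_allclose(w, [0.8, 0.2])

    def test_beyond_threshold_gets_zero(self):
        w = dispersal_weights(np.array([10.0, 200.0]), d_max=100, d_floor=1)
        assert w[1] == 0.0
        assert w[0] == 1.0

    def test_single_candidate_and_no_candidate(self):
        assert dispersal_weights(np.array([42.0]), 100, 1)[0] == 1.0
        assert dispersal_weights(np.array([200.0]), 100, 1) is None

    def test_zero_distance_uses_floor(self):
        w = dispersal_weights(np.array([0.0, 5.0]), d_max=100, d_floor=5.0)
        np.testing.assert_allclose(w, [0.5, 0.5])

    @pytest.mark.parametrize(
        "count,s,h,expected",
        [(0, 0.3, 0.5, 1.0), (1, 0.3, 0.5, 1.15), (2, 0.3, 0.5, 1.3), (2, 0.0, 0.5, 1.0)],
    )
    def test_viability_weights(self, count, s, h, expected):
        assert viability_weights(count, s, h) == pytest.approx(expected)


class TestStepYear:
    def test_population_never_exceeds_locations_and_locations_fixed(self):
        state = line_state(40, seed=2)
        before = state.locations.copy()
        cfg = basic_config(d_max=1e6, d_floor=1.0, s=0.2, scenario="preexisting")
        init_preexisting_allele(state, 0.2, seed=2)
        rng = np.random.default_rng(0)
        for _ in range(30):
            step_year(state, flat_cost(40), cfg, rng)
            assert state.pop_size <= 40
        np.testing.assert_array_equal(state.locations, before)

    def test_no_new_allele_states_without_mutation(self):
        rng = np.random.default_rng(8)
        m = 30
        state = line_state(m, seed=8)
        state.neutral = rng.choice([100, 102, 104], size=(m, 5, 2)).astype(np.int32)
        initial_states = {frozenset(np.unique(state.neutral[:, l])) for l in range(5)}
        cfg = basic_config()
        for _ in range(20):
            step_year(state, flat_cost(m), cfg, rng)
        occ = state.occupied
        for l in range(5):
            assert set(np.unique(state.neutral[occ, l])) <= {100, 102, 104}
        assert initial_states  # loci kept their original state alphabets

    def test_unreachable_vacancies_make_population_nonincreasing(self):
        state = line_state(30, seed=1)
        cfg = SimConfig(d_max=1e-9, d_floor=1e-9)
        rng = np.random.default_rng(3)
        sizes = [state.pop_size]
        for _ in range(10):
            step_year(state, flat_cost(30), cfg, rng)
            sizes.append(state.pop_size)
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_mean_fA_nondecreasing_in_selection_strength(self):
        """Stronger selection cannot lower the expected allele frequency."""
        m = 60
        means = []
        for s in (0.0, 0.3):
            cfg = SimConfig(
                d_max=1e9, d_floor=1.0, s=s, scenario="preexisting", p0=0.2,
                years=30, n_replicates=60, seed=77,
            )
            res = run_experiment(line_state(m).locations, flat_cost(m), cfg)
            final = res.fA[:, -1]
            means.append(np.nanmean(final))
        se = 0.03  # conservative MC allowance at 60 replicates
        assert means[1] >= means[0] - 3 * se
        assert means[1] > means[0]  # s = 0.3 visibly beats drift here


class TestRunExperiment:
    def test_record_bookkeeping_and_year_zero(self):
        cfg = SimConfig(
            d_max=1e9, d_floor=1.0, scenario="preexisting", p0=0.1,
            years=3, n_replicates=2, seed=5,
        )
        res = run_experiment(line_state(20).locations, flat_cost(20), cfg)
        assert res.fA.shape == (2, 4)
        assert res.pop_size.shape == (2, 4)
        assert np.all(res.fA[:, 0] == pytest.approx(0.1))

    def test_deterministic_given_base_seed(self):
        cfg = SimConfig(
            d_max=1e9, d_floor=1.0, s=0.1, scenario="novel",
            years=5, n_replicates=3, seed=42,
        )
        locs = line_state(50).locations
        a = run_experiment(locs, flat_cost(50), cfg)
        b = run_experiment(locs, flat_cost(50), cfg)
        np.testing.assert_array_equal(a.fA, b.fA)
        np.testing.assert_array_equal(a.presence, b.presence)

    def test_extinction_recorded(self):
        cfg = SimConfig(
            d_max=1e9, d_floor=1.0, scenario="preexisting", p0=0.1,
            years=5, n_replicates=2, seed=1,
            mortality=np.ones(17), fecundity=np.full(17, 0.9),
        )
        res = run_experiment(line_state(10).locations, flat_cost(10), cfg)
        assert np.all(res.extinct)


class TestConfig:
    def test_threshold_bracketing_matches_printed_values(self):
        low, mid, high = bracket_dispersal_thresholds(534861)
        assert (low, mid, high) == (267430, 534861, 1069722)

    def test_scenario_defaults_for_p0(self):
        assert basic_config(scenario="novel").p0 == 0.01
        assert basic_config(scenario="preexisting").p0 == 0.05

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            basic_config(s=-0.1)
        with pytest.raises(ConfigurationError):
            basic_config(h=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(d_max=0.0, d_floor=1.0)
        with pytest.raises(ConfigurationError):
            basic_config(mortality=np.zeros(5))

    def test_default_mortality_schedule_shape(self):
        m = default_mortality()
        assert len(m) == 17
        assert m[0] == pytest.approx(0.40)
        assert m[16] == pytest.approx(0.50)
        assert np.all((m >= 0) & (m <= 1))
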