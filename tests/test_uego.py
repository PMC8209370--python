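"""Tests for the multimodal optimizer: geometry, species dynamics, SASS."""

import math

import numpy as np
import pytest

from adexfit import (
    DEFAULT_BOUNDS,
    AdExParameters,
    Species,
    UEGOConfig,
    create_species,
    denormalize,
    fuse_population,
    init_population,
    level_schedule,
    normalize,
    run_uego,
    sass_search,
    shorten_population,
    unit_diameter,
)


def sphere_objective(optimum):
    optimum = np.asarray(optimum, dtype=float)
    return lambda x: float(np.sum((x - optimum) ** 2))


def bimodal_objective(x):
    """Two equal-depth wells at 0.2 and 0.8 in a 1-d unit interval."""
    x = float(np.asarray(x).ravel()[0])
    return min((x - 0.2) ** 2, (x - 0.8) ** 2)


class TestNormalization:
    def test_bound_corners(self):
        lower = AdExParameters.from_array(DEFAULT_BOUNDS.lower)
        upper = AdExParameters.from_array(DEFAULT_BOUNDS.upper)
        assert np.allclose(normalize(lower, DEFAULT_BOUNDS), 0.0)
        assert np.allclose(normalize(upper, DEFAULT_BOUNDS), 1.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.random(10)
            back = normalize(denormalize(x, DEFAULT_BOUNDS), DEFAULT_BOUNDS)
            assert np.allclose(back, x, atol=1e-12)

    def test_unit_diameter(self):
        assert unit_diameter(10) == pytest.approx(math.sqrt(10.0), abs=1e-12)

    def test_out_of_bounds_rejected(self):
        params = AdExParameters.from_array(DEFAULT_BOUNDS.upper)
        bigger = AdExParameters.from_array(params.to_array() * 1.1)
        with pytest.raises(ValueError):
            normalize(bigger, DEFAULT_BOUNDS)
        with pytest.raises(ValueError):
            denormalize(np.full(10, 1.5), DEFAULT_BOUNDS)


class TestLevelSchedule:
    def test_geometric_radii_with_exact_endpoints(self):
        config = UEGOConfig(max_species=100, max_evaluations=10_000_000,
                            min_radius=0.7, levels=50)
        diameter = unit_diameter(10)
        sched = level_schedule(config, diameter)
        assert sched.radii[0] == pytest.approx(diameter)
        assert sched.radii[-1] == pytest.approx(0.7)
        ratios = sched.radii[1:] / sched.radii[:-1]
        assert np.allclose(ratios, ratios[0])
        assert np.all(np.diff(sched.radii) < 0)

    def test_creation_budget_is_three_m_from_level_two(self):
        config = UEGOConfig(max_species=100, levels=50)
        sched = level_schedule(config, unit_diameter(10))
        assert sched.creation[0] == 0
        assert np.all(sched.creation[1:] == 300)

    def test_budgets_within_global_cap(self):
        config = UEGOConfig(max_species=20, max_evaluations=20_000, levels=10,
                            min_radius=0.7)
        sched = level_schedule(config, unit_diameter(10))
        total = int(sched.creation.sum() + sched.optimization.sum()) + 1
        assert total <= config.max_evaluations
        assert np.all(np.diff(sched.optimization) >= 0)  # later levels get more

    def test_single_level_degenerates_to_local_search_budget(self):
        sched = level_schedule(UEGOConfig(levels=1, max_evaluations=100),
                               unit_diameter(2))
        assert sched.levels == 1
        assert sched.optimization[0] == 99

    def test_min_radius_beyond_diameter_rejected(self):
        with pytest.raises(ValueError):
            level_schedule(UEGOConfig(min_radius=3.0), unit_diameter(2))


class TestInitPopulation:
    def test_single_full_diameter_species(self):
        rng = np.random.default_rng(0)
        calls = []

        def objective(x):
            calls.append(x.copy())
            return float(np.sum(x))

        pop = init_population(objective, 10, unit_diameter(10), rng)
        assert len(pop) == 1
        assert pop[0].radius == pytest.approx(unit_diameter(10))
        assert len(calls) == 1

    def test_seeded_determinism(self):
        objective = sphere_objective(np.full(10, 0.5))
        a = init_population(objective, 10, unit_diameter(10), np.random.default_rng(7))
        b = init_population(objective, 10, unit_diameter(10), np.random.default_rng(7))
        assert np.array_equal(a[0].center, b[0].center)


class TestCreateSpecies:
    def test_convex_objective_creates_nothing(self):
        """On a convex quadratic no midpoint is ever worse than both
        endpoints, so no pair can signal separate basins."""
        objective = sphere_objective(np.full(2, 0.5))
        for seed in range(5):
            pop = [Species(np.full(2, 0.5), 0.0, unit_diameter(2))]
            create_species(pop, 0.5, 30, objective, np.random.default_rng(seed))
            assert len(pop) == 1

    def test_two_well_objective_spawns_species(self):
        pop = [Species(np.array([0.5]), bimodal_objective(np.array([0.5])), 1.0)]
        used = create_species(pop, 0.2, 30, bimodal_objective,
                              np.random.default_rng(0))
        assert used <= 30
        assert len(pop) > 1
        assert all(sp.radius == 0.2 for sp in pop[1:])

    def test_center_moves_to_better_sample(self):
        objective = sphere_objective(np.array([0.9, 0.9]))
        start = np.array([0.2, 0.2])
        pop = [Species(start.copy(), objective(start), unit_diameter(2))]
        create_species(pop, 0.5, 30, objective, np.random.default_rng(3))
        assert pop[0].fitness < objective(start)

    def test_starved_budget_creates_nothing(self):
        objective = sphere_objective(np.array([0.5]))
        pop = [Species(np.array([0.4]), objective(np.array([0.4])), 1.0)]
        used = create_species(pop, 2, 2, objective, np.random.default_rng(0))
        assert used == 0
        assert len(pop) == 1


class TestFusePopulation:
    def test_overlapping_pair_keeps_better_center_and_larger_radius(self):
        a = Species(np.zeros(10), 5.0, math.sqrt(10.0))
        center_b = np.zeros(10)
        center_b[0] = 0.3
        b = Species(center_b, 3.0, 0.9)
        pop = fuse_population([a, b], 0.7)
        assert len(pop) == 1
        assert np.array_equal(pop[0].center, center_b)
        assert pop[0].fitness == 3.0
        assert pop[0].radius == math.sqrt(10.0)

    def test_distant_pair_untouched(self):
        a = Species(np.zeros(2), 1.0, 1.0)
        b = Species(np.ones(2), 2.0, 1.0)
        pop = fuse_population([a, b], 0.7)
        assert len(pop) == 2

    def test_all_pairwise_distances_separated_afterwards(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pop = [
                Species(rng.random(3), float(rng.random()), 0.5 + rng.random())
                for _ in range(12)
            ]
            fuse_population(pop, 0.4)
            for i in range(len(pop)):
                for j in range(i + 1, len(pop)):
                    d = np.linalg.norm(pop[i].center - pop[j].center)
                    assert d >= 0.4


class TestShortenPopulation:
    def test_removes_shortest_radii_first(self):
        rng = np.random.default_rng(5)
        pop = [Species(rng.random(2), float(i), 1.0 + i) for i in range(103)]
        rng.shuffle(pop)
        shorten_population(pop, 100)
        assert len(pop) == 100
        assert min(sp.radius for sp in pop) == pytest.approx(4.0)  # radii 1..3 gone

    def test_noop_when_within_limit(self):
        pop = [Species(np.zeros(2), 0.0, 1.0)]
        assert len(shorten_population(pop, 100)) == 1

    def test_full_diameter_species_survives(self):
        rng = np.random.default_rng(6)
        diameter = unit_diameter(2)
        pop = [Species(rng.random(2), 0.0, diameter)]
        pop += [Species(rng.random(2), float(rng.random()), 0.3) for _ in range(30)]
        shorten_population(pop, 10)
        assert any(sp.radius == diameter for sp in pop)

    def test_radius_ties_drop_worse_fitness(self):
        pop = [
            Species(np.zeros(2), 1.0, 0.5),
            Species(np.ones(2), 9.0, 0.5),
            Species(np.full(2, 0.5), 2.0, 2.0),
        ]
        shorten_population(pop, 2)
        assert all(sp.fitness != 9.0 for sp in pop)


class TestSASS:
    def test_constant_objective_terminates_after_32_failures(self):
        species = Species(np.full(10, 0.5), 1.0, 1.0)
        calls = []

        def constant(x):
            calls.append(1)
            return 1.0

        result = sass_search(species, 1.0, 10_000, constant, np.random.default_rng(0))
        assert result.evaluations == 32
        assert len(calls) == 32

    def test_sigma_doubles_after_five_consecutive_successes(self):
        species = Species(np.full(5, 0.5), 1000.0, 1.0)
        state = {"v": 1000.0}

        def improving(x):
            state["v"] -= 1.0
            return state["v"]

        result = sass_search(species, 0.01, 5, improving,
                             np.random.default_rng(0), sigma_init=0.25)
        assert result.sigma == pytest.approx(0.5)

    def test_sigma_clamped_at_upper_bound(self):
        species = Species(np.full(5, 0.5), 1000.0, 1.0)
        state = {"v": 1000.0}

        def improving(x):
            state["v"] -= 1.0
            return state["v"]

        result = sass_search(species, 0.01, 10, improving, np.random.default_rng(0))
        assert result.sigma == 1.0

    def test_sigma_halves_every_three_consecutive_failures(self):
        species = Species(np.full(10, 0.5), 1.0, 1.0)
        result = sass_search(species, 1.0, 10_000, lambda x: 1.0,
                             np.random.default_rng(0))
        # 32 failures -> 10 halvings, still above the 1e-5 clamp
        assert result.sigma == pytest.approx(2.0 ** -10)

    def test_sigma_clamped_at_lower_bound(self):
        species = Species(np.full(10, 0.5), 1.0, 1.0)
        result = sass_search(species, 1.0, 10_000, lambda x: 1.0,
                             np.random.default_rng(0), sigma_init=2e-5)
        assert result.sigma == pytest.approx(1e-5)

    def test_accepted_displacements_bounded_by_step_bound(self):
        step_bound = 0.25
        species = Species(np.full(10, 0.5), math.inf, step_bound)
        centers = [species.center.copy()]

        def accept_all(x):
            centers.append(np.asarray(x).copy())
            return -float(len(centers))  # strictly improving

        sass_search(species, step_bound, 200, accept_all, np.random.default_rng(1))
        for prev, cur in zip(centers, centers[1:]):
            assert np.linalg.norm(cur - prev) <= step_bound + 1e-12

    def test_budget_respected(self):
        species = Species(np.full(3, 0.5), math.inf, 1.0)
        count = []

        def noisy(x):
            count.append(1)
            return float(np.sum(x))

        result = sass_search(species, 1.0, 17, noisy, np.random.default_rng(2))
        assert result.evaluations <= 17
        assert len(count) == result.evaluations


class TestRunUEGO:
    def test_single_level_returns_one_optimized_species(self):
        config = UEGOConfig(max_species=10, max_evaluations=500, min_radius=0.1,
                            levels=1, seed=0)
        pop, ledger = run_uego(sphere_objective([0.3, 0.7]), 2, config)
        assert len(pop) == 1
        assert ledger.total <= 500
        assert pop[0].fitness < 0.1

    def test_sphere_optimum_found(self):
        config = UEGOConfig(max_species=10, max_evaluations=5000, min_radius=0.1,
                            levels=5, seed=0)
        pop, ledger = run_uego(sphere_objective([0.3, 0.7]), 2, config)
        assert min(sp.fitness for sp in pop) <= 1e-3
        assert ledger.total <= 5000

    def test_bimodal_finds_both_wells(self):
        config = UEGOConfig(max_species=10, max_evaluations=3000, min_radius=0.2,
                            levels=6, seed=0)
        pop, _ = run_uego(bimodal_objective, 1, config)
        assert len(pop) >= 2
        centers = np.array([float(sp.center[0]) for sp in pop])
        assert np.min(np.abs(centers - 0.2)) <= 0.1
        assert np.min(np.abs(centers - 0.8)) <= 0.1

    def test_equal_seeds_give_bit_identical_populations(self):
        config = UEGOConfig(max_species=10, max_evaluations=4000, min_radius=0.1,
                            levels=5, seed=123)
        pop_a, ledger_a = run_uego(sphere_objective([0.3, 0.7]), 2, config)
        pop_b, ledger_b = run_uego(sphere_objective([0.3, 0.7]), 2, config)
        assert len(pop_a) == len(pop_b)
        for a, b in zip(pop_a, pop_b):
            assert np.array_equal(a.center, b.center)
            assert a.fitness == b.fitness
            assert a.radius == b.radius
        assert ledger_a.per_level == ledger_b.per_level

    def test_exceptions_in_objective_become_penalty(self):
        def flaky(x):
            if x[0] > 0.5:
                raise RuntimeError("boom")
            return float(np.sum(x))

        config = UEGOConfig(max_species=5, max_evaluations=500, min_radius=0.2,
                            levels=3, seed=0)
        pop, ledger = run_uego(flaky, 2, config)
        assert len(pop) >= 1
        assert all(np.isfinite(sp.fitness) for sp in pop)
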