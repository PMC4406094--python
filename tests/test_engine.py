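import numpy as np
import pytest

from dmscape import (
    FEMALE,
    MALE,
    Extent,
    FitnessModel,
    LociConfig,
    OffspringPool,
    Population,
    ScenarioConfig,
    build_movement_kernel,
    build_neighbor_index,
    disperse_and_select,
    dm_fitness,
    founding_population,
    generate_sites,
    genotype_class_index,
    kernel_weights,
    reproduce,
    select_mate,
    select_mates,
    step_generation,
)
from dmscape.engine import default_distance_floor


def _tiny_world(n=60, seed=5, radius=8.0):
    sites = generate_sites(n, Extent(20.0, 15.0), seed=seed)
    index = build_neighbor_index(sites, radius)
    kernel = build_movement_kernel(index, default_distance_floor(sites))
    return sites, kernel


def _uniform_pop(n, sex, rng, loci=LociConfig()):
    from dmscape import initial_genotypes

    return Population(
        occupied=np.ones(n, dtype=bool),
        sex=np.asarray(sex, dtype=np.int8),
        genotypes=initial_genotypes(n, loci, rng),
    )


class TestKernelWeights:
    def test_single_candidate_gets_probability_one(self):
        assert kernel_weights([2.0], dmax=5.0) == pytest.approx([1.0])

    def test_equal_distances_split_evenly(self):
        np.testing.assert_allclose(kernel_weights([3.0, 3.0], dmax=5.0), [0.5, 0.5])

    def test_inverse_square_ratio(self):
        np.testing.assert_allclose(kernel_weights([1.0, 2.0], dmax=5.0), [0.8, 0.2])

    def test_normalization_is_tight(self):
        rng = np.random.default_rng(0)
        w = kernel_weights(rng.uniform(0.1, 5.0, size=200), dmax=5.0)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_beyond_dmax_rejected(self):
        with pytest.raises(ValueError):
            kernel_weights([6.0], dmax=5.0)

    def test_zero_distance_needs_floor(self):
        with pytest.raises(ValueError):
            kernel_weights([0.0], dmax=5.0)
        w = kernel_weights([0.0, 1.0], dmax=5.0, d_floor=0.5)
        assert w[0] > w[1]

    def test_empty_candidates_signal_no_candidates(self):
        assert kernel_weights([], dmax=5.0).size == 0


class TestSelectMate:
    def test_no_male_in_range_returns_none(self, rng):
        sites, kernel = _tiny_world()
        pop = _uniform_pop(60, [FEMALE] * 60, rng)
        mothers, fathers = select_mates(pop, kernel, rng)
        assert (fathers == -1).all()

    def test_single_male_always_chosen(self, rng):
        sites, kernel = _tiny_world()
        sex = np.full(60, FEMALE)
        sex[10] = MALE
        pop = _uniform_pop(60, sex, rng)
        nb, _ = (kernel.indices[kernel.indptr[0]:kernel.indptr[1]], None)
        if 10 in nb:
            assert select_mate(0, pop, kernel, rng) == 10

    def test_mate_draw_frequencies_follow_inverse_square(self, rng):
        """Empirical mate frequencies match the kernel on a 3-male fixture."""
        coords = np.array([[5.0, 5.0], [6.0, 5.0], [7.0, 5.0], [5.0, 8.0]])
        from dmscape import SiteMap

        sites = SiteMap(coords=coords, extent=Extent(20.0, 20.0))
        index = build_neighbor_index(sites, 10.0)
        kernel = build_movement_kernel(index, default_distance_floor(sites))
        pop = _uniform_pop(4, [FEMALE, MALE, MALE, MALE], rng)
        d = np.array([1.0, 2.0, 3.0])
        want = (1 / d**2) / (1 / d**2).sum()
        draws = np.array([select_mate(0, pop, kernel, rng) for _ in range(20_000)])
        got = np.array([(draws == i).mean() for i in (1, 2, 3)])
        np.testing.assert_allclose(got, want, atol=0.015)

    def test_males_reused_with_replacement(self, rng):
        sites, kernel = _tiny_world()
        sex = np.full(60, FEMALE)
        sex[0] = MALE
        pop = _uniform_pop(60, sex, rng)
        _, fathers = select_mates(pop, kernel, rng)
        assert (fathers[fathers >= 0] == 0).all()
        assert (fathers >= 0).sum() > 1


class TestReproduce:
    def test_lambda_zero_gives_empty_pool(self, rng):
        pop = _uniform_pop(10, [FEMALE] * 5 + [MALE] * 5, rng)
        pool = reproduce(np.arange(5), np.arange(5, 10), pop, 0.0, LociConfig(), rng)
        assert pool.size == 0

    def test_unmated_females_excluded(self, rng):
        pop = _uniform_pop(4, [FEMALE, FEMALE, MALE, MALE], rng)
        pool = reproduce(np.array([0, 1]), np.array([2, -1]), pop, 4.0, LociConfig(), rng)
        assert (pool.natal == 0).all()

    def test_pool_size_matches_poisson_sum(self, rng):
        n_f = 2500
        pop = _uniform_pop(2 * n_f, [FEMALE] * n_f + [MALE] * n_f, rng)
        pool = reproduce(
            np.arange(n_f), np.arange(n_f, 2 * n_f), pop, 4.0, LociConfig(), rng
        )
        assert abs(pool.size - 4 * n_f) < 3 * np.sqrt(4 * n_f)

    def test_pure_class_cross_yields_only_AaBb(self, rng):
        loci = LociConfig(mutation_rate=0.0)
        pop = _uniform_pop(2, [FEMALE, MALE], rng, loci)
        pop.genotypes[0, 1, :] = 1  # mother AABB
        pop.genotypes[1, 0, :] = 1  # father aabb
        pop.genotypes[1, 1, :] = 0
        pool = reproduce(np.array([0]), np.array([1]), pop, 50.0, loci, rng)
        from dmscape import GENOTYPE_CLASSES

        assert (genotype_class_index(pool.genotypes) == GENOTYPE_CLASSES.index("AaBb")).all()


class TestDisperseAndSelect:
    def test_single_viable_offspring_settles(self, rng):
        sites, kernel = _tiny_world()
        loci = LociConfig()
        pool = OffspringPool(
            genotypes=np.zeros((1, loci.n_loci, 2), dtype=np.int8),
            sex=np.array([0], dtype=np.int8),
            natal=np.array([3], dtype=np.int64),
        )
        pop = disperse_and_select(pool, kernel, FitnessModel(), 60, rng)
        assert pop.size == 1

    def test_inviable_pool_leaves_empty_population(self, rng):
        sites, kernel = _tiny_world()
        loci = LociConfig()
        g = np.zeros((40, loci.n_loci, 2), dtype=np.int8)
        g[:, 0, 0] = 1  # Aa
        g[:, 1, 0] = 1  # Bb -> AaBb, inviable
        pool = OffspringPool(
            genotypes=g,
            sex=np.zeros(40, dtype=np.int8),
            natal=rng.integers(0, 60, size=40),
        )
        assert (dm_fitness(g) == 0).all()
        pop = disperse_and_select(pool, kernel, FitnessModel(), 60, rng)
        assert pop.size == 0

    def test_at_most_one_individual_per_site(self, rng):
        sites, kernel = _tiny_world()
        loci = LociConfig()
        pool = OffspringPool(
            genotypes=np.zeros((300, loci.n_loci, 2), dtype=np.int8),
            sex=rng.integers(0, 2, 300).astype(np.int8),
            natal=rng.integers(0, 60, size=300),
        )
        pop = disperse_and_select(pool, kernel, FitnessModel(), 60, rng)
        assert pop.size <= 60
        # surplus pool and full reach: every site should fill
        assert pop.size == 60

    def test_philopatry_prefers_natal_site(self, rng):
        sites, kernel = _tiny_world()
        loci = LociConfig()
        pool = OffspringPool(
            genotypes=np.zeros((1, loci.n_loci, 2), dtype=np.int8),
            sex=np.array([0], dtype=np.int8),
            natal=np.array([7], dtype=np.int64),
        )
        pop = disperse_and_select(pool, kernel, FitnessModel(), 60, rng)
        assert pop.occupied[7]


class TestStepGeneration:
    def test_fixed_seed_is_bit_identical(self):
        cfg = ScenarioConfig(movement_fraction=0.3, n_sites=150, generations=1,
                             seed=9, area=300.0, max_distance=30.0)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(cfg.seed)
            sites = generate_sites(cfg.n_sites, Extent(20.0, 15.0), rng)
            index = build_neighbor_index(sites, cfg.dmax)
            kernel = build_movement_kernel(index, default_distance_floor(sites))
            pop = founding_population(cfg, rng)
            for _ in range(3):
                pop = step_generation(pop, cfg, kernel, rng)
            runs.append(pop)
        a, b = runs
        assert (a.occupied == b.occupied).all()
        assert (a.sex == b.sex).all()
        assert (a.genotypes == b.genotypes).all()

    def test_single_sex_population_collapses(self, rng):
        cfg = ScenarioConfig(movement_fraction=1.0, n_sites=60, generations=1,
                             area=300.0, max_distance=30.0)
        sites = generate_sites(60, Extent(20.0, 15.0), rng)
        index = build_neighbor_index(sites, cfg.dmax)
        kernel = build_movement_kernel(index, default_distance_floor(sites))
        pop = _uniform_pop(60, [MALE] * 60, rng)
        nxt = step_generation(pop, cfg, kernel, rng)
        assert nxt.size == 0
        # stepping an empty population stays empty and advances the counter
        after = step_generation(nxt, cfg, kernel, rng)
        assert after.size == 0 and after.generation == nxt.generation + 1

    def test_selection_invariant_no_survivor_carries_a_and_B(self, rng):
        """After every generation, nobody carries >=1 a and >=1 B."""
        cfg = ScenarioConfig(movement_fraction=0.2, n_sites=300, generations=1,
                             seed=13, area=300.0, max_distance=30.0,
                             loci=LociConfig(mutation_rate=0.01))
        rng2 = np.random.default_rng(cfg.seed)
        sites = generate_sites(cfg.n_sites, Extent(20.0, 15.0), rng2)
        index = build_neighbor_index(sites, cfg.dmax)
        kernel = build_movement_kernel(index, default_distance_floor(sites))
        pop = founding_population(cfg, rng2)
        for _ in range(25):
            pop = step_generation(pop, cfg, kernel, rng2)
            g = pop.alive_genotypes()
            if len(g) == 0:
                break
            has_a = g[:, 0, :].sum(axis=1) >= 1
            has_B = g[:, 1, :].sum(axis=1) >= 1
            assert not (has_a & has_B).any()
            assert pop.occupied.sum() == pop.size <= cfg.n_sites
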