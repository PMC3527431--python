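import numpy as np
import pytest

from grnevo import (
    GrnError,
    MeltdownError,
    Population,
    SimConfig,
    develop_batch,
    fitness,
    make_offspring_pool,
    mutate,
    random_network,
    recombine,
    run_simulation,
    select_survivors,
)
from grnevo.evolution import _truncate, log_fitness_batch


@pytest.fixture
def founder_pop(stable_founder):
    net, s0 = stable_founder
    return Population.from_founder(net, s0, 250)


class TestRecombine:
    def test_identical_parents_identity(self, rng, stable_founder):
        net, _ = stable_founder
        child = recombine(net, net, rng)
        assert child == net

    def test_rows_inherited_whole(self, rng):
        a = random_network(10, 0.75, rng)
        b = a.copy()
        b.weights[b.mask] = rng.standard_normal(b.n_links)
        for _ in range(50):
            child = recombine(a, b, rng)
            for i in range(10):
                row = child.weights[i]
                assert np.array_equal(row, a.weights[i]) or np.array_equal(
                    row, b.weights[i]
                )

    def test_row_origin_is_fair_coin(self, rng):
        a = random_network(10, 0.75, rng)
        b = a.copy()
        b.weights[b.mask] = rng.standard_normal(b.n_links)
        n_trials, from_a = 1000, 0
        for _ in range(n_trials):
            child = recombine(a, b, rng)
            from_a += sum(
                np.array_equal(child.weights[i], a.weights[i]) for i in range(10)
            )
        total = n_trials * 10
        p_hat = from_a / total
        # 4 sigma binomial band around 1/2
        assert abs(p_hat - 0.5) < 4 * np.sqrt(0.25 / total)

    def test_mask_mismatch_rejected(self, rng):
        a = random_network(10, 0.75, rng)
        b = random_network(10, 0.75, rng)
        while np.array_equal(a.mask, b.mask):
            b = random_network(10, 0.75, rng)
        with pytest.raises(GrnError):
            recombine(a, b, rng)


class TestMutate:
    def test_zero_rate_identity(self, rng, stable_founder):
        net, _ = stable_founder
        assert mutate(net, 0.0, rng) == net

    def test_expected_genome_rate(self, rng, stable_founder):
        """With mu=0.1 and 75 loci the per-offspring expectation is 0.1
        mutations, i.e. 100 entering a 1000-offspring pool."""
        net, _ = stable_founder
        n_off = 20_000
        changed = 0
        batch = np.repeat(net.weights[None], n_off, axis=0)
        from grnevo.evolution import _mutate_batch_inplace

        _mutate_batch_inplace(batch, net.mask, 0.1 / 75, rng)
        changed = (batch != net.weights[None]).sum()
        mean_per_offspring = changed / n_off
        se = np.sqrt(0.1 / n_off)  # ~Poisson
        assert abs(mean_per_offspring - 0.1) < 4 * se

    def test_per_element_hit_probability(self, rng, stable_founder):
        net, _ = stable_founder
        p = 0.1 / 75
        n_off = 14_000  # ~1e6 element-trials over 75 loci
        batch = np.repeat(net.weights[None], n_off, axis=0)
        from grnevo.evolution import _mutate_batch_inplace

        _mutate_batch_inplace(batch, net.mask, p, rng)
        trials = n_off * 75
        hits = (batch != net.weights[None]).sum()
        p_hat = hits / trials
        assert abs(p_hat - p) < 4 * np.sqrt(p * (1 - p) / trials)

    def test_zero_elements_never_mutate(self, rng, stable_founder):
        net, _ = stable_founder
        for _ in range(20):
            out = mutate(net, 5.0, rng)  # extreme rate
            assert np.all(out.weights[~net.mask] == 0.0)
            assert np.array_equal(out.mask, net.mask)


class TestFitness:
    def test_perfect_match(self):
        s = np.linspace(-1, 1, 10)
        assert fitness(s, s) == 1.0

    def test_reference_value(self):
        # D = 0.05 at sigma = 0.05 gives exactly 1/e
        s1 = np.zeros(10)
        s2 = np.zeros(10)
        s2[0] = np.sqrt(2.0)  # D = 2/40 = 0.05
        assert fitness(s1, s2, sigma=0.05) == pytest.approx(np.exp(-1.0))

    def test_monotone_decreasing_in_distance(self, rng):
        s = np.zeros(10)
        prev = fitness(s, s)
        for shift in np.linspace(0.1, 1.0, 10):
            f = fitness(s, np.full(10, shift))
            assert f < prev
            prev = f


class TestSelection:
    def test_truncation_matches_exhaustive_sort(self, rng):
        for _ in range(20):
            logf = rng.normal(size=1000)
            idx = _truncate(logf, 250, rng)
            assert len(set(idx.tolist())) == 250
            expected = set(np.argsort(-logf)[:250].tolist())
            assert set(idx.tolist()) == expected

    def test_survivor_fitness_dominates_culled(self, rng, founder_pop):
        cfg = SimConfig(generations=1)
        pool = make_offspring_pool(founder_pop, cfg, rng)
        opt = rng.uniform(-1, 1, 10)
        logf = log_fitness_batch(pool.phenotypes, opt, 0.05)
        idx = _truncate(logf, 250, rng)
        culled = np.setdiff1d(np.arange(1000), idx)
        assert logf[idx].min() >= logf[culled].max()

    def test_clone_pool_any_subset_survives(self, rng, stable_founder, founder_pop):
        net, s0 = stable_founder
        cfg = SimConfig(mu=0.0)
        pool = make_offspring_pool(founder_pop, cfg, rng)
        surv = select_survivors(
            pool, founder_pop.phenotypes[0], 250, rng, mask=net.mask, s0=s0
        )
        assert surv.size == 250
        assert np.all(surv.weights == net.weights[None])

    def test_undersized_pool_rejected(self, rng, founder_pop):
        cfg = SimConfig(pop_size=10, pool_size=20, mu=0.0)
        pool = make_offspring_pool(founder_pop, cfg, rng)
        with pytest.raises(GrnError):
            select_survivors(pool, founder_pop.phenotypes[0], 250, rng)


class TestOffspringPool:
    def test_sexual_clones_under_zero_mutation(self, rng, stable_founder, founder_pop):
        net, _ = stable_founder
        cfg = SimConfig(mu=0.0)
        pool = make_offspring_pool(founder_pop, cfg, rng)
        assert pool.weights.shape == (1000, 10, 10)
        assert np.all(pool.weights == net.weights[None])
        assert np.all(pool.stability < 1e-4)

    def test_pool_exactly_filled_and_viable(self, rng, founder_pop):
        cfg = SimConfig()
        pool = make_offspring_pool(founder_pop, cfg, rng)
        assert pool.weights.shape[0] == 1000
        assert np.all(pool.stability < 1e-4)
        assert pool.attempts >= 1000
        # re-develop survivors independently: stability must agree
        _, v, viable, _ = develop_batch(pool.weights, founder_pop.s0)
        assert np.all(viable)
        assert np.allclose(v, pool.stability)

    def test_asexual_offspring_clone_some_parent(self, rng, stable_founder):
        net, s0 = stable_founder
        pop = Population.from_founder(net, s0, 50)
        # distinct parents: perturb each member at one locus
        ii, jj = np.nonzero(net.mask)
        pop.weights[np.arange(50), ii[:50], jj[:50]] += 0.5
        phen, v, viable, _ = develop_batch(pop.weights, s0)
        pop.phenotypes = phen
        pop.weights = pop.weights[viable]
        pop.phenotypes = pop.phenotypes[viable]
        cfg = SimConfig(mu=0.0, reproduction="asexual", pop_size=10, pool_size=100)
        pool = make_offspring_pool(pop, cfg, rng)
        parents = {w.tobytes() for w in pop.weights}
        for w in pool.weights:
            assert w.tobytes() in parents

    def test_meltdown_raises(self, rng, founder_pop):
        # V < 0 never holds, so no offspring can ever be viable
        cfg = SimConfig(stability_threshold=0.0, attempt_cap_factor=1, pool_size=250)
        with pytest.raises(MeltdownError) as err:
            make_offspring_pool(founder_pop, cfg, rng, generation=17)
        assert err.value.generation == 17


class TestRunSimulation:
    def test_static_population_under_stabilizing_no_mutation(self, stable_founder):
        net, s0 = stable_founder
        cfg = SimConfig(mu=0.0, generations=30, assay_every=10)
        res = run_simulation(cfg, founder=(net, s0), seed=5)
        assert np.all(res.mean_log_fitness == 0.0)
        assert np.all(res.population.weights == net.weights[None])
        m = res.metrics.pivot(index="generation", columns="metric", values="value")
        assert np.all(m["allelic_diversity"] == 1.0)
        assert np.all(m["phenotypic_diversity"] == 1.0)
        assert np.all(m["matrix_change"] == 0.0)

    def test_seed_determinism_whole_engine(self):
        cfg = SimConfig(regime="red", period=50, generations=25, assay_every=25)
        r1 = run_simulation(cfg, seed=9)
        r2 = run_simulation(cfg, seed=9)
        assert np.array_equal(r1.mean_log_fitness, r2.mean_log_fitness)
        assert np.array_equal(r1.population.weights, r2.population.weights)
        assert r1.metrics.equals(r2.metrics)

    def test_topology_conserved_and_population_sized(self):
        cfg = SimConfig(regime="white", period=10, generations=40, assay_every=40)
        res = run_simulation(cfg, seed=3)
        pop = res.population
        assert pop.size == 250
        assert np.array_equal(pop.mask, res.founder.mask)
        off_mask = ~res.founder.mask
        assert np.all(pop.weights[:, off_mask] == 0.0)
        _, _, viable, _ = develop_batch(pop.weights, pop.s0)
        assert np.all(viable)
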