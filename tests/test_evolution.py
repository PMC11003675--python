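"""Engine tests: selection arithmetic, drift, survival filtering, runs."""

import numpy as np
import pytest

from serann.evolution import (
    DegeneratePopulationError, ExtinctionError, StubModel,
    absolute_fitness, produce_next_generation, relative_fertility,
    relative_fitness, run_experiment, sample_offspring_counts,
    select_ancestor,
)


class TestSelectionArithmetic:
    def test_equal_fertility_gives_uniform(self):
        f = relative_fertility(np.full(8, 0.7))
        assert np.allclose(f, 1 / 8)

    def test_direct_normalisation(self):
        assert np.allclose(relative_fertility([0.9, 0.1]), [0.9, 0.1])

    def test_sums_to_one(self, rng):
        f = relative_fertility(rng.random(50))
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(DegeneratePopulationError):
            relative_fertility(np.zeros(5))

    def test_absolute_fitness(self):
        assert absolute_fitness(1.0, 0.42) == 0.42
        assert absolute_fitness(0.0, 0.9) == 0.0
        # the published worked example: V = 0.063, F = 0.96
        assert absolute_fitness(0.063, 0.96) == pytest.approx(0.06048)

    def test_relative_fitness(self):
        assert relative_fitness(1.0, 0.5, 0.5) == 1.0
        assert relative_fitness(1.0, 0.8, 0.4) == pytest.approx(2.0)


class TestOffspringCounts:
    def test_sum_is_population_size(self, rng):
        f = relative_fertility(rng.random(20))
        for _ in range(50):
            assert sample_offspring_counts(f, 37, rng).sum() == 37

    def test_degenerate_distribution(self, rng):
        f = np.zeros(6)
        f[0] = 1.0
        counts = sample_offspring_counts(f, 11, rng)
        assert counts[0] == 11 and counts[1:].sum() == 0

    def test_multinomial_mean(self, rng):
        f = relative_fertility([0.5, 0.3, 0.2])
        N, reps = 30, 10_000
        draws = np.stack([sample_offspring_counts(f, N, rng)
                          for _ in range(reps)])
        for i in range(3):
            se = np.sqrt(N * f[i] * (1 - f[i]) / reps)
            assert abs(draws[:, i].mean() - N * f[i]) < 3 * se


class _PerParentSurvivalModel(StubModel):
    """Offspring viability depends on which parent's genotype it carries
    (parent identity is one-hot encoded in the genotype)."""

    def __init__(self, survivals, **kw):
        super().__init__(**kw)
        self.survivals = survivals

    def make(self, genotype, rng):
        from serann.individual import StubIndividual
        parent = int(np.argmax(genotype))
        if rng.random() >= self.survivals[parent]:
            return None
        return StubIndividual(np.asarray(genotype, dtype=np.uint8))


class TestSurvivalExpectation:
    def test_expected_surviving_offspring(self, rng):
        """E[surviving offspring of parent i] = N * V_i * f_i, checked over
        10,000 replicate generations with stub individuals of fixed V and F."""
        F = np.array([0.9, 0.6, 0.3])
        V = np.array([1.0, 0.7, 0.4])
        f = relative_fertility(F)
        N, P, reps = 24, 3, 10_000
        pools = [np.tile(np.eye(P, dtype=np.uint8)[i], (5, 1))
                 for i in range(P)]
        model = _PerParentSurvivalModel(V)
        totals = np.zeros(P)
        for _ in range(reps):
            _, _, counts, surv_init, _, _ = produce_next_generation(
                pools, f, N, model, rng)
            totals += surv_init
        expected = N * V * f
        # binomial-compound variance: Var = N f V (1 - f V) per generation
        for i in range(P):
            var = N * f[i] * V[i] * (1 - f[i] * V[i])
            se = np.sqrt(var / reps)
            assert abs(totals[i] / reps - expected[i]) < 3 * se


class TestNextGeneration:
    def test_perfect_replicators_copy_parents(self, rng):
        P, N, k = 4, 12, 10
        genos = rng.integers(0, 2, (P, k)).astype(np.uint8)
        pools = [np.tile(genos[i], (6, 1)) for i in range(P)]
        f = np.full(P, 0.25)
        model = StubModel()
        offspring, parents, counts, *_ = produce_next_generation(
            pools, f, N, model, rng)
        assert len(offspring) == N
        assert counts.sum() == N
        for child, p in zip(offspring, parents):
            assert np.array_equal(child.genotype, genos[p])

    def test_extinction_when_nothing_survives(self, rng):
        class DeadModel(StubModel):
            def make(self, genotype, rng):
                return None

        pools = [np.zeros((5, 4), dtype=np.uint8)]
        with pytest.raises(ExtinctionError):
            produce_next_generation(pools, np.array([1.0]), 8, DeadModel(), rng)


class TestRunExperiment:
    def test_smoke_run_shape_and_conservation(self):
        model = StubModel(fertility=0.8, flip_prob=0.02, pool_size=20)
        anc = np.zeros(12, dtype=np.uint8)
        res = run_experiment(model, anc, N=16, G=10, seed=3)
        assert len(res.records) == 10
        for rec in res.records:
            assert len(rec.genotypes) == 16
            assert sum(rec.f) == pytest.approx(1.0, abs=1e-9)
            assert sum(rec.offspring_counts) == 16
            for Ni, Si in zip(rec.offspring_counts, rec.surviving_counts):
                assert 0 <= Si <= Ni
        assert res.final_genotypes.shape == (16, 12)

    def test_seeded_reproducibility(self):
        anc = np.zeros(10, dtype=np.uint8)
        runs = []
        for _ in range(2):
            model = StubModel(fertility=1.0, flip_prob=0.05, pool_size=15)
            res = run_experiment(model, anc, N=12, G=6, seed=11)
            runs.append([rec.genotypes for rec in res.records])
        assert runs[0] == runs[1]

    def test_isogenic_start_richness_one(self):
        model = StubModel(flip_prob=0.1, pool_size=10)
        res = run_experiment(model, np.ones(8, dtype=np.uint8), N=10, G=1,
                             seed=0)
        assert len(set(res.records[0].genotypes)) == 1

    def test_drift_neutrality(self):
        """With mutation off and equal fertility, the mean final frequency of
        a neutral genotype over 2,000 replicate populations equals its
        initial frequency (unbiased random walk)."""
        N, G, reps = 20, 5, 2000
        anc = np.stack([np.zeros(6, dtype=np.uint8),
                        np.ones(6, dtype=np.uint8)])
        finals = np.empty(reps)
        for rep in range(reps):
            model = StubModel(pool_size=10)
            res = run_experiment(model, anc, N=N, G=G, seed=100_000 + rep)
            last = res.final_genotypes
            finals[rep] = (last.sum(axis=1) == 0).mean()
        # variance of a Wright-Fisher neutral walk after G generations
        var = 0.25 * (1 - (1 - 1 / N) ** G)
        se = np.sqrt(var / reps)
        assert abs(finals.mean() - 0.5) < 3 * se


def test_select_ancestor_prefers_viable_candidate():
    class GenotypeSurvivalModel(StubModel):
        def make(self, genotype, rng):
            # genotypes starting with 1 rarely produce viable offspring
            if genotype[0] == 1 and rng.random() > 0.3:
                return None
            from serann.individual import StubIndividual
            return StubIndividual(np.asarray(genotype, dtype=np.uint8))

    good = np.zeros(6, dtype=np.uint8)
    bad = np.ones(6, dtype=np.uint8)
    idx, chosen = select_ancestor(GenotypeSurvivalModel(pool_size=10),
                                  np.stack([bad, good]), N=10, G=3, seed=2)
    assert idx == 1
    assert np.array_equal(chosen, good)
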