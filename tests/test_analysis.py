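"""Estimator tests: mutation rate, DFE, robustness, epistasis, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serann.analysis import (
    dfe_from_records, epistasis_scan, estimate_mutation_rate,
    fitness_effects_dfe, mutagen_comparison, mutational_robustness,
    permutation_corr_pvalue, repeated_evaluation,
    trajectories_and_fixation, variance_to_mean_ratio,
)
from serann.evolution import GenerationRecord, StubModel


class TestMutationRate:
    def test_identical_offspring_zero(self):
        g = np.array([1, 0, 1, 0], dtype=np.uint8)
        spec = estimate_mutation_rate(g, np.tile(g, (7, 1)))
        assert spec.mu == 0.0
        assert np.all(spec.per_site == 0)

    def test_hand_hamming_example(self):
        g = np.zeros(4, dtype=np.uint8)
        off = np.array([[0, 0, 0, 1], [0, 0, 1, 1]], dtype=np.uint8)
        assert estimate_mutation_rate(g, off).mu == pytest.approx(1.5)

    def test_per_site_fraction(self):
        g = np.zeros(5, dtype=np.uint8)
        off = np.zeros((10, 5), dtype=np.uint8)
        off[:3, 2] = 1
        spec = estimate_mutation_rate(g, off)
        assert spec.per_site[2] == pytest.approx(0.3)
        assert spec.mu == pytest.approx(spec.per_site.sum())

    def test_matches_bruteforce_hamming_oracle(self, rng):
        g = rng.integers(0, 2, 30).astype(np.uint8)
        off = rng.integers(0, 2, (50, 30)).astype(np.uint8)
        total = sum(int(np.sum(g != o)) for o in off)  # brute force
        assert estimate_mutation_rate(g, off).mu * 50 == pytest.approx(total)

    def test_no_offspring_flagged(self):
        with pytest.raises(ValueError):
            estimate_mutation_rate(np.zeros(4), np.zeros((0, 4)))


class TestDFE:
    @pytest.mark.parametrize("wp,wm,effect,label", [
        (0.8, 0.0, 0.0, "lethal"),
        (0.8, 0.8, 1.0, "neutral"),
        (0.8, 0.9, 1.125, "beneficial"),
        (0.8, 0.4, 0.5, "deleterious"),
    ])
    def test_classification(self, wp, wm, effect, label):
        s = fitness_effects_dfe([(wp, wm)])
        assert s.effects[0] == pytest.approx(effect)
        assert s.labels == [label]

    def test_zero_parent_excluded_and_counted(self):
        s = fitness_effects_dfe([(0.0, 0.5), (0.8, 0.8)])
        assert len(s.effects) == 1
        assert s.n_excluded_zero_parent == 1

    def test_class_proportions_sum_to_one(self, rng):
        pairs = [(0.5 + 0.4 * rng.random(), 0.9 * rng.random())
                 for _ in range(100)]
        props = fitness_effects_dfe(pairs).class_proportions()
        assert sum(props.values()) == pytest.approx(1.0)


class TestRobustness:
    def test_optimal_parent_all_lethal_is_zero(self):
        assert mutational_robustness(1.0, [(0.0, 3), (0.0, 7)]) == 0.0

    def test_all_neutral_is_one(self):
        assert mutational_robustness(0.64, [(0.64, 2), (0.64, 5)]) == 1.0

    def test_weighted_example(self):
        # W_g = 0.8; mutants (0.8, M=3) and (0.3, M=1): 1 - 0.5/4
        lam = mutational_robustness(0.8, [(0.8, 3), (0.3, 1)])
        assert lam == pytest.approx(0.875)

    def test_no_mutants_flagged(self):
        with pytest.raises(ValueError):
            mutational_robustness(0.5, [])


def _simulate(h, k, seed, a12=0.0, sigma=0.05, backgrounds=None):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 2, (h, k)).astype(float)
    beta = rng.normal(0, 0.05, k)
    F = 0.5 + G @ beta + rng.normal(0, sigma, h)
    if a12:
        F = F + a12 * G[:, 0] * G[:, 1]
    return G, F


class TestEpistasisScan:
    def test_mle_matches_lstsq_oracle(self, rng):
        G, F = _simulate(80, 6, seed=1)
        table = epistasis_scan(G, F)
        for _, row in table[table.tested].iterrows():
            i, j = int(row.site_i), int(row.site_j)
            X = np.column_stack([np.ones(len(F)), G[:, i], G[:, j],
                                 G[:, i] * G[:, j]])
            beta, *_ = np.linalg.lstsq(X, F, rcond=None)
            assert row.b == pytest.approx(beta[0], abs=1e-8)
            assert row.a_i == pytest.approx(beta[1], abs=1e-8)
            assert row.a_j == pytest.approx(beta[2], abs=1e-8)
            assert row.a_ij == pytest.approx(beta[3], abs=1e-8)

    def test_number_of_tests_for_100_sites(self):
        G, F = _simulate(150, 100, seed=2)
        table = epistasis_scan(G, F)
        assert len(table) == 9900
        assert int(table.tested.sum()) == 9900

    def test_lrt_invariant_to_affine_fertility_rescaling(self):
        G, F = _simulate(60, 5, seed=3)
        t1 = epistasis_scan(G, F)
        t2 = epistasis_scan(G, 100.0 * F + 7.0)
        assert np.allclose(t1.lrt[t1.tested], t2.lrt[t2.tested], atol=1e-8)

    def test_planted_interaction_recovered(self):
        """a_12 = 0.05 planted at n = 5,000 with sigma_F = 0.01 is estimated
        within +/-0.01 and significant after FDR."""
        G, F = _simulate(5000, 6, seed=4, a12=0.05, sigma=0.01)
        table = epistasis_scan(G, F)
        row = table[(table.site_i == 0) & (table.site_j == 1)].iloc[0]
        assert row.a_ij == pytest.approx(0.05, abs=0.01)
        assert row.qvalue < 0.05

    def test_fdr_calibrated_under_additive_null(self):
        """Under a purely additive model, the fraction of datasets with any
        q < 0.05 discovery stays near the FDR level."""
        false_positive_runs = 0
        n_runs = 200
        for s in range(n_runs):
            G, F = _simulate(100, 6, seed=1000 + s)
            table = epistasis_scan(G, F)
            false_positive_runs += (table.qvalue[table.tested] < 0.05).any()
        # Bernoulli(0.05) bound with 3 SE of Monte-Carlo slack
        assert false_positive_runs / n_runs < 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / n_runs)

    def test_monomorphic_site_skipped(self, rng):
        G, F = _simulate(50, 4, seed=5)
        G[:, 2] = 1.0
        table = epistasis_scan(G, F)
        sub = table[(table.site_i == 2) | (table.site_j == 2)]
        assert (~sub.tested).all()
        assert (sub.skip_reason == "monomorphic-site").all()

    def test_too_few_genotypes_rejected(self, rng):
        with pytest.raises(ValueError):
            epistasis_scan(np.zeros((5, 4)), np.zeros(5))


def _records_from_freqs(freqs, k=1):
    """Build a minimal one-site log with given derived-allele frequencies."""
    records = []
    n = 10
    for t, p in enumerate(freqs):
        ones = int(round(p * n))
        genotypes = ["1" * k] * ones + ["0" * k] * (n - ones)
        records.append(GenerationRecord(
            t=t, genotypes=genotypes, spec_texts=[None] * n,
            F=[1.0] * n, f=[0.1] * n, offspring_counts=[1] * n,
            surviving_counts=[1] * n, drawn_total=[1] * n,
            survived_total=[1] * n, parent_index=list(range(n)),
            alpha=[None] * n, pool_survival=[None] * n))
    return records


class TestTrajectories:
    def test_fixation_time_from_constructed_log(self):
        records = _records_from_freqs([0.2, 0.6, 1.0])
        freq, fix, rich = trajectories_and_fixation(records, "0")
        assert np.allclose(freq[0].to_numpy(), [0.2, 0.6, 1.0])
        assert fix.loc[0, "fixation_time"] == 2
        assert fix.loc[0, "fixation_time_90"] == 2

    def test_no_mutation_all_zero(self):
        records = _records_from_freqs([0.0, 0.0, 0.0])
        freq, fix, _ = trajectories_and_fixation(records, "0")
        assert (freq.to_numpy() == 0).all()
        assert fix.loc[0, "fixation_time"] is None

    def test_distinct_population_richness(self, rng):
        n, k = 8, 12
        genotypes = ["".join(map(str, rng.integers(0, 2, k)))
                     for _ in range(n)]
        assert len(set(genotypes)) == n
        rec = GenerationRecord(
            t=0, genotypes=genotypes, spec_texts=[None] * n, F=[1.0] * n,
            f=[1 / n] * n, offspring_counts=[1] * n, surviving_counts=[1] * n,
            drawn_total=[1] * n, survived_total=[1] * n,
            parent_index=list(range(n)), alpha=[None] * n,
            pool_survival=[None] * n)
        _, _, rich = trajectories_and_fixation([rec], "0" * k)
        assert rich.loc[0, "genotype_richness"] == n

    def test_gap_in_log_rejected(self):
        records = _records_from_freqs([0.1, 0.2])
        records[1].t = 5
        with pytest.raises(ValueError, match="gap"):
            trajectories_and_fixation(records, "0")


class TestRepeatedEvaluation:
    def test_deterministic_stub_zero_variance(self):
        model = StubModel(fertility=0.77, pool_size=8)
        res = repeated_evaluation(model, np.zeros(6, dtype=np.uint8),
                                  cycles=10, seed=0)
        assert res.F_mean == pytest.approx(0.77)
        assert res.F_sd == pytest.approx(0.0, abs=1e-12)

    def test_known_accuracy_recovered(self):
        model = StubModel(fertility=0.35, pool_size=8)
        res = repeated_evaluation(model, np.zeros(6, dtype=np.uint8),
                                  cycles=50, seed=1)
        assert res.F_mean == pytest.approx(0.35, abs=1e-12)

    def test_cycles_must_be_positive(self):
        with pytest.raises(ValueError):
            repeated_evaluation(StubModel(), np.zeros(4), cycles=0, seed=0)

    def test_permutation_pvalues_uniform_under_null(self):
        """Independence null: permutation p-values are uniform on [0, 1]
        (Kolmogorov-Smirnov, alpha = 0.01)."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(120):
            x, y = rng.normal(size=20), rng.normal(size=20)
            _, p = permutation_corr_pvalue(x, y, n_perm=499, rng=rng)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class _CondStub:
    """Stub whose bit-flip rate depends on the image condition (mean pixel)."""

    def __init__(self, genotype, base_rate, seed):
        self.genotype = genotype
        self.base_rate = base_rate
        self.seed = seed

    def mutation_rate_under(self, images, rng):
        rate = self.base_rate * (2.0 if images.mean() > 0.5 else 1.0)
        k, n = len(self.genotype), images.shape[0]
        local = np.random.default_rng(self.seed)  # fixed trained state
        flips = local.random((n, k)) < rate
        return flips.sum(axis=1).mean()


class TestMutagenComparison:
    def test_identical_conditions_ratio_one(self):
        rng = np.random.default_rng(0)
        inds = [_CondStub(np.zeros(20, dtype=np.uint8), 0.1, s)
                for s in range(5)]
        imgs = np.full((50, 4, 4), 0.2)
        out = mutagen_comparison(inds, imgs, imgs.copy())
        # same deterministic per-individual estimator under both conditions
        assert out["t_statistic"] == pytest.approx(0.0, abs=2.0)

    def test_doubled_flip_rate_recovered(self):
        inds = [_CondStub(np.zeros(50, dtype=np.uint8), 0.08, s)
                for s in range(20)]
        imgs_a = np.full((1000, 4, 4), 0.2)
        imgs_b = np.full((1000, 4, 4), 0.9)
        out = mutagen_comparison(inds, imgs_a, imgs_b)
        assert out["ratio"] == pytest.approx(2.0, rel=0.1)
        assert out["pvalue"] < 0.01

    def test_difference_arithmetic_identity(self):
        inds = [_CondStub(np.zeros(30, dtype=np.uint8), 0.05, s)
                for s in range(6)]
        out = mutagen_comparison(inds, np.full((200, 3, 3), 0.1),
                                 np.full((200, 3, 3), 0.8))
        assert out["differences"].sum() == pytest.approx(
            (out["mean_b"] - out["mean_a"]) * len(inds))

    def test_fewer_than_two_individuals_rejected(self):
        with pytest.raises(ValueError):
            mutagen_comparison([_CondStub(np.zeros(4), 0.1, 0)],
                               np.zeros((5, 2, 2)), np.zeros((5, 2, 2)))


def test_variance_to_mean_ratio_poisson_limit(rng):
    """Independent per-site flips give mutation counts with VMR near 1."""
    k, n = 40, 300
    parent = "0" * k
    rec0 = GenerationRecord(
        t=0, genotypes=[parent] * n, spec_texts=[None] * n, F=[1.0] * n,
        f=[1 / n] * n, offspring_counts=[1] * n, surviving_counts=[1] * n,
        drawn_total=[1] * n, survived_total=[1] * n,
        parent_index=list(range(n)), alpha=[None] * n,
        pool_survival=[None] * n)
    children = []
    for _ in range(n):
        bits = (rng.random(k) < 0.05).astype(int)
        children.append("".join(map(str, bits)))
    rec1 = GenerationRecord(
        t=1, genotypes=children, spec_texts=[None] * n, F=[1.0] * n,
        f=[1 / n] * n, offspring_counts=[1] * n, surviving_counts=[1] * n,
        drawn_total=[1] * n, survived_total=[1] * n,
        parent_index=list(range(n)), alpha=[None] * n,
        pool_survival=[None] * n)
    out = variance_to_mean_ratio([rec0, rec1])
    assert out.loc[0, "mean_mutations"] == pytest.approx(2.0, rel=0.25)
    assert out.loc[0, "vmr"] == pytest.approx(1.0, abs=0.3)
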