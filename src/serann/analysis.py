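"""Estimators and statistics over evolution runs.

Covers: per-genotype mutation rate (mean Hamming distance to offspring),
offspring survival, the distribution of fitness effects (DFE), mutational
robustness, a pairwise epistasis likelihood-ratio scan with FDR correction,
allele-frequency trajectories and fixation times, repeated
initialise-train-evaluate cycles for phenotypic-variation estimates, and the
random-image "mutagen" comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evolution import GenerationRecord

__all__ = [
    "MutationSpectrum", "DFESample", "EpistasisPair", "EvaluationCycleResult",
    "estimate_mutation_rate", "estimate_survival_rate",
    "fitness_effects_dfe", "dfe_from_records", "mutational_robustness",
    "epistasis_scan", "trajectories_and_fixation",
    "variance_to_mean_ratio", "repeated_evaluation",
    "permutation_corr_pvalue", "mutagen_comparison",
]


@dataclass(frozen=True)
class MutationSpectrum:
    """Mutation-rate estimate for one genotype.

    ``mu`` is the mean Hamming distance between the genotype and its
    offspring; ``per_site`` the fraction of offspring mutated at each site,
    so ``mu == per_site.sum()``.
    """

    mu: float
    per_site: np.ndarray
    n_offspring: int


def estimate_mutation_rate(g: np.ndarray, offspring: np.ndarray) -> MutationSpectrum:
    """mu_g = (1/N_g) * sum_j H(g, g'_j), with the per-site spectrum."""
    g = np.asarray(g, dtype=np.uint8)
    offspring = np.atleast_2d(np.asarray(offspring, dtype=np.uint8))
    if offspring.shape[0] == 0:
        raise ValueError("mutation rate undefined without offspring")
    if offspring.shape[1] != g.shape[0]:
        raise ValueError("offspring genotype length mismatch")
    diff = offspring != g
    per_site = diff.mean(axis=0)
    return MutationSpectrum(float(per_site.sum()), per_site, offspring.shape[0])


def estimate_survival_rate(offspring: np.ndarray, codec, build=None) -> float:
    """Fraction of offspring genotypes that decode to buildable specs.

    Individuals over the parameter cap are counted as surviving (they enter
    the population sterile), matching the engine's survival rule.
    """
    from .netspec import build_network
    from .riboae import decode

    offspring = np.atleast_2d(np.asarray(offspring, dtype=np.uint8))
    ok = 0
    for g in offspring:
        rep = build_network(decode(g, codec).text, build)
        ok += rep.valid or rep.error_kind == "parameter-cap-exceeded"
    return ok / offspring.shape[0]


def _classify_effect(ratio: float) -> str:
    if ratio == 0.0:
        return "lethal"
    if ratio < 1.0:
        return "deleterious"
    if ratio == 1.0:
        return "neutral"
    return "beneficial"


@dataclass
class DFESample:
    """Fitness effects W_mutant / W_parent with class labels."""

    effects: np.ndarray
    labels: list[str]
    window: tuple[int, int]
    n_excluded_zero_parent: int = 0

    def class_proportions(self) -> dict[str, float]:
        n = len(self.labels)
        return {c: self.labels.count(c) / n
                for c in ("lethal", "deleterious", "neutral", "beneficial")}


def fitness_effects_dfe(pairs, window: tuple[int, int] = (0, 0),
                        sample_size: int | None = None,
                        rng: np.random.Generator | None = None) -> DFESample:
    """Fitness effects from (W_parent, W_mutant) pairs.

    Pairs with zero parent fitness are excluded and counted.  If more pairs
    than ``sample_size`` are available, a uniform subsample is taken.
    """
    pairs = [(float(p), float(m)) for p, m in pairs]
    kept = [(p, m) for p, m in pairs if p > 0]
    excluded = len(pairs) - len(kept)
    if sample_size is not None and len(kept) > sample_size:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(kept), size=sample_size, replace=False)
        kept = [kept[i] for i in idx]
    effects = np.array([m / p for p, m in kept])
    labels = [_classify_effect(e) for e in effects]
    return DFESample(effects, labels, window, excluded)


def dfe_from_records(records: list[GenerationRecord], window: int = 1000,
                     per_window: int = 5000,
                     rng: np.random.Generator | None = None) -> list[DFESample]:
    """Parent-mutant fitness-effect samples per generation window.

    A pair is a (parent at t, child at t+1) link whose genotypes differ in at
    least one site; fitness is W = V * F with the record's best survival
    estimate.
    """
    rng = rng or np.random.default_rng(0)
    by_window: dict[int, list[tuple[float, float]]] = {}
    for rec, nxt in zip(records[:-1], records[1:]):
        W_par, W_child = rec.W, nxt.W
        for child_i, par_i in enumerate(nxt.parent_index):
            if nxt.genotypes[child_i] == rec.genotypes[par_i]:
                continue
            wp, wc = W_par[par_i], W_child[child_i]
            if wp is None or wc is None:
                continue
            by_window.setdefault(rec.t // window, []).append((wp, wc))
    out = []
    for w, pairs in sorted(by_window.items()):
        out.append(fitness_effects_dfe(
            pairs, window=(w * window, (w + 1) * window),
            sample_size=per_window, rng=rng))
    return out


def mutational_robustness(W_g: float, mutants) -> float:
    """lambda(g) = 1 - sum |W_g' - W_g| M_{g->g'} / sum M_{g->g'}.

    ``mutants`` is an iterable of (W_mutant, multiplicity).  0 for an optimal
    genotype with only lethal mutants, 1 when all mutants are neutral.
    Raises if the genotype has no recorded mutants.
    """
    mutants = [(float(w), int(m)) for w, m in mutants]
    total = sum(m for _, m in mutants)
    if total <= 0:
        raise ValueError("robustness undefined without recorded mutants")
    weighted = sum(abs(w - W_g) * m for w, m in mutants)
    return 1.0 - weighted / total


@dataclass(frozen=True)
class EpistasisPair:
    """Fitted interaction model for one ordered site pair."""

    site_i: int
    site_j: int
    b: float
    a_i: float
    a_j: float
    a_ij: float
    sigma_F: float
    loglik_full: float
    loglik_reduced: float
    lrt: float
    pvalue: float
    qvalue: float


def epistasis_scan(G: np.ndarray, F: np.ndarray) -> pd.DataFrame:
    """Pairwise-interaction scan over all ordered site pairs i != j.

    For each pair, the fertility model F = b + a_i g_i + a_j g_j +
    a_ij g_i g_j + Normal(0, sigma_F) is fitted by maximum likelihood
    (equivalently least squares), compared by likelihood-ratio test against
    the additive model (a_ij = 0), with the chi-square(1) asymptotic null and
    Benjamini-Hochberg FDR correction over all performed tests.  The model is
    symmetric in (i, j); both orderings are enumerated and reported.

    Pairs where a site is monomorphic or some allele combination is absent
    (singular design) are skipped with a reason.  Returns a DataFrame with
    one row per ordered pair.
    """
    G = np.asarray(G, dtype=float)
    F = np.asarray(F, dtype=float)
    h, k = G.shape
    if h <= 10:
        raise ValueError("need more than 10 genotypes")
    S = G.sum(axis=0)                       # per-site carrier counts
    Sij = G.T @ G                           # joint carrier counts
    SF = float(F.sum())
    SFi = G.T @ F
    SFij = (G * F[:, None]).T @ G
    SFF = float((F ** 2).sum())

    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    mask_off = ii != jj
    i_idx, j_idx = ii[mask_off], jj[mask_off]

    n11 = Sij[i_idx, j_idx]
    n1x, nx1 = S[i_idx], S[j_idx]
    n10 = n1x - n11
    n01 = nx1 - n11
    n00 = h - n1x - nx1 + n11
    testable = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    mono = (n1x == 0) | (n1x == h) | (nx1 == 0) | (nx1 == h)

    n_pairs = i_idx.size
    out = {
        "site_i": i_idx, "site_j": j_idx,
        "b": np.full(n_pairs, np.nan), "a_i": np.full(n_pairs, np.nan),
        "a_j": np.full(n_pairs, np.nan), "a_ij": np.full(n_pairs, np.nan),
        "sigma_F": np.full(n_pairs, np.nan),
        "loglik_full": np.full(n_pairs, np.nan),
        "loglik_reduced": np.full(n_pairs, np.nan),
        "lrt": np.full(n_pairs, np.nan), "pvalue": np.full(n_pairs, np.nan),
        "qvalue": np.full(n_pairs, np.nan),
        "tested": testable.copy(),
        "skip_reason": np.where(testable, "",
                                np.where(mono, "monomorphic-site",
                                         "empty-allele-combination")),
    }

    t_i, t_j = i_idx[testable], j_idx[testable]
    nt = t_i.size
    if nt:
        si, sj, sij = S[t_i], S[t_j], Sij[t_i, t_j]
        XtX = np.empty((nt, 4, 4))
        XtX[:, 0] = np.stack([np.full(nt, float(h)), si, sj, sij], axis=1)
        XtX[:, 1] = np.stack([si, si, sij, sij], axis=1)
        XtX[:, 2] = np.stack([sj, sij, sj, sij], axis=1)
        XtX[:, 3] = np.stack([sij, sij, sij, sij], axis=1)
        Xty = np.stack([np.full(nt, SF), SFi[t_i], SFi[t_j],
                        SFij[t_i, t_j]], axis=1)
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        rss_full = np.maximum(SFF - (beta * Xty).sum(axis=1), 1e-300)
        beta_red = np.linalg.solve(XtX[:, :3, :3], Xty[:, :3, None])[..., 0]
        rss_red = np.maximum(SFF - (beta_red * Xty[:, :3]).sum(axis=1), 1e-300)

        def loglik(rss):
            return -0.5 * h * (np.log(2 * np.pi * rss / h) + 1.0)

        ll_full, ll_red = loglik(rss_full), loglik(rss_red)
        lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        pvals = stats.chi2.sf(lrt, df=1)
        qvals = multipletests(pvals, method="fdr_bh")[1]

        out["b"][testable] = beta[:, 0]
        out["a_i"][testable] = beta[:, 1]
        out["a_j"][testable] = beta[:, 2]
        out["a_ij"][testable] = beta[:, 3]
        out["sigma_F"][testable] = np.sqrt(rss_full / h)
        out["loglik_full"][testable] = ll_full
        out["loglik_reduced"][testable] = ll_red
        out["lrt"][testable] = lrt
        out["pvalue"][testable] = pvals
        out["qvalue"][testable] = qvals
    return pd.DataFrame(out)


def trajectories_and_fixation(records: list[GenerationRecord],
                              ancestor: np.ndarray | str,
                              fixation_threshold: float = 1.0):
    """Derived-allele frequencies per site per generation, fixation times at
    the default threshold and at 90%, and genotype/phenotype richness.

    Returns (freq DataFrame indexed by generation, fixation DataFrame with one
    row per site, richness DataFrame).  Raises on a gap in the generation
    index.
    """
    if isinstance(ancestor, str):
        anc = np.array([int(c) for c in ancestor], dtype=np.uint8)
    else:
        anc = np.asarray(ancestor, dtype=np.uint8)
    ts = [r.t for r in records]
    if ts != list(range(ts[0], ts[0] + len(ts))):
        raise ValueError("generation log has gaps")
    freqs, rich = [], []
    for rec in records:
        mat = np.array([[int(c) for c in g] for g in rec.genotypes],
                       dtype=np.uint8)
        freqs.append((mat != anc).mean(axis=0))
        rich.append({
            "t": rec.t,
            "genotype_richness": len(set(rec.genotypes)),
            "phenotype_richness": len({s for s in rec.spec_texts
                                       if s is not None}),
        })
    freq = pd.DataFrame(np.stack(freqs), index=ts)
    freq.index.name = "t"

    def first_cross(col: np.ndarray, thr: float):
        hit = np.nonzero(col >= thr)[0]
        return int(ts[hit[0]]) if hit.size else None

    fix_rows = []
    arr = freq.to_numpy()
    for site in range(arr.shape[1]):
        fix_rows.append({
            "site": site,
            "fixation_time": first_cross(arr[:, site], fixation_threshold),
            "fixation_time_90": first_cross(arr[:, site], 0.9),
            "max_frequency": float(arr[:, site].max()),
        })
    return freq, pd.DataFrame(fix_rows), pd.DataFrame(rich)


def variance_to_mean_ratio(records: list[GenerationRecord]) -> pd.DataFrame:
    """Per-generation variance-to-mean ratio of offspring mutation counts.

    Mutation counts are Hamming distances between each individual and its
    parent in the previous generation's record.
    """
    rows = []
    for prev, rec in zip(records[:-1], records[1:]):
        counts = []
        for i, p in enumerate(rec.parent_index):
            a = rec.genotypes[i]
            b = prev.genotypes[p]
            counts.append(sum(x != y for x, y in zip(a, b)))
        counts = np.array(counts, dtype=float)
        mean = counts.mean()
        rows.append({
            "t": rec.t, "mean_mutations": mean,
            "vmr": float(counts.var(ddof=1) / mean) if mean > 0 else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationCycleResult:
    """Repeated initialise-train-evaluate cycles for one genotype."""

    accuracies: np.ndarray
    survival_rates: np.ndarray
    replicated_sample: np.ndarray | None = None

    @property
    def F_mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def F_sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def V_mean(self) -> float:
        return float(self.survival_rates.mean())

    @property
    def V_sd(self) -> float:
        return float(self.survival_rates.std(ddof=1)) if len(self.survival_rates) > 1 else 0.0


def repeated_evaluation(model, genotype: np.ndarray, cycles: int,
                        seed: int) -> EvaluationCycleResult:
    """Independent initialise-train-evaluate cycles with distinct substreams.

    Each cycle develops the genotype, re-initialises and trains its network,
    measures classification accuracy, and estimates offspring survival from
    the replicated-genotype pool.  A cycle whose genotype fails to develop
    contributes accuracy 0 and survival 0.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    accs, survs = [], []
    sample = None
    for c in range(cycles):
        rng = np.random.default_rng(np.random.SeedSequence((seed, c)))
        ind = model.make(np.asarray(genotype, dtype=np.uint8), rng)
        if ind is None:
            accs.append(0.0)
            survs.append(0.0)
            continue
        model.mature(ind, rng)
        accs.append(model.fertility(ind))
        pool = model.pool(ind, rng)
        if hasattr(model, "pool_validity"):
            survs.append(model.pool_validity(pool))
        else:
            survs.append(1.0)
        if sample is None:
            sample = pool[: min(10, pool.shape[0])].copy()
    return EvaluationCycleResult(np.array(accs), np.array(survs), sample)


def permutation_corr_pvalue(x: np.ndarray, y: np.ndarray, n_perm: int = 10000,
                            rng: np.random.Generator | None = None
                            ) -> tuple[float, float]:
    """Pearson correlation and a two-sided permutation p-value."""
    rng = rng or np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        r = float(np.corrcoef(x, rng.permutation(y))[0, 1])
        if abs(r) >= abs(r_obs):
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def _mu_under(ind, images: np.ndarray, rng: np.random.Generator) -> float:
    """Mean Hamming distance of replicated genotypes under an image set."""
    if hasattr(ind, "mutation_rate_under"):
        return float(ind.mutation_rate_under(images, rng))
    from .individual import predict
    G = np.tile(ind.genotype.astype(float), (images.shape[0], 1))
    _, g_prime = predict(ind, images, G)
    off = (g_prime > 0.5).astype(np.uint8)
    return estimate_mutation_rate(ind.genotype, off).mu


def mutagen_comparison(individuals, images_a: np.ndarray, images_b: np.ndarray,
                       rng: np.random.Generator | None = None) -> dict:
    """Paired comparison of mutation rates under two input-image conditions.

    Same genotypes and trained states under both conditions; returns the
    per-condition means, their ratio (B over A), per-individual differences,
    and a paired t-test across individuals.
    """
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals for a paired test")
    rng = rng or np.random.default_rng(0)
    mu_a = np.array([_mu_under(ind, images_a, rng) for ind in individuals])
    mu_b = np.array([_mu_under(ind, images_b, rng) for ind in individuals])
    if np.allclose(mu_a, mu_b):
        tstat, pval = 0.0, 1.0
    else:
        tstat, pval = stats.ttest_rel(mu_b, mu_a)
    return {
        "mu_a": mu_a, "mu_b": mu_b,
        "mean_a": float(mu_a.mean()), "mean_b": float(mu_b.mean()),
        "ratio": float(mu_b.mean() / mu_a.mean()) if mu_a.mean() > 0 else np.inf,
        "differences": mu_b - mu_a,
        "t_statistic": float(tstat), "pvalue": float(pval),
    }
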