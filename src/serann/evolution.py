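"""Wright-Fisher engine: fertility selection, drift, decoding, survival.

One generation (constant population size N, non-overlapping generations):

1. every individual is trained on the dual task (development),
2. evaluated on the shared test set to obtain fertility F_i and a pool of
   potential offspring genotypes,
3. relative fertility f_i = F_i / sum_j F_j determines the expected
   contribution to the next generation,
4. offspring counts N_i ~ Multinomial(N, f) (drift),
5. each of the N_i offspring genotypes is drawn from parent i's pool
   (with replacement),
6. each offspring genotype is decoded to a spec; only buildable specs
   survive.

Constant N is reconciled with survival deaths by conditional resampling: a
dead offspring is replaced by redrawing a parent proportionally to f and one
member of its pool, until N valid offspring exist or a retry budget of 50*N
draws is exhausted (extinction).  This preserves E[surviving offspring of i]
proportional to V_i * f_i while keeping the census size constant.

Individuals over the trainable-parameter cap stay in the population but have
fertility forced to 0, so they leave no offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .individual import (
    Environment, Individual, StubIndividual, TrainConfig,
    evaluate_fertility, self_replicate, train_individual,
)
from .netspec import BuildConfig, build_network
from .riboae import CodecState, decode

__all__ = [
    "DegeneratePopulationError", "ExtinctionError",
    "GenerationRecord", "RunResult",
    "relative_fertility", "sample_offspring_counts",
    "absolute_fitness", "relative_fitness",
    "CodecModel", "StubModel", "produce_next_generation",
    "run_experiment", "select_ancestor",
]

RESAMPLE_BUDGET_FACTOR = 50

# seed-stream tags so every random draw is reproducible from (seed, t)
_TAG_DRIFT, _TAG_TRAIN, _TAG_POOL, _TAG_INIT = 0, 1, 2, 3


class DegeneratePopulationError(RuntimeError):
    """All fertilities are zero; relative fertility is undefined."""


class ExtinctionError(RuntimeError):
    """Survival was so low the resampling budget was exhausted."""

    def __init__(self, msg, records=None):
        super().__init__(msg)
        self.records = records or []


def relative_fertility(F: np.ndarray) -> np.ndarray:
    """f_i = F_i / sum_j F_j.  Raises on an all-zero population."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("fertilities must be non-negative")
    total = F.sum()
    if total <= 0:
        raise DegeneratePopulationError("all fertilities are zero")
    return F / total


def sample_offspring_counts(f: np.ndarray, N: int,
                            rng: np.random.Generator) -> np.ndarray:
    """N_i ~ Multinomial(N, f): non-negative integers summing to N."""
    return rng.multinomial(N, np.asarray(f, dtype=float))


def absolute_fitness(V: float, F: float) -> float:
    """W = V * F: offspring survival rate times fertility."""
    return V * F


def relative_fitness(V: float, F: float, F_bar: float) -> float:
    """w = V * F / F_bar: expected per-generation change in frequency."""
    if F_bar <= 0:
        raise ValueError("mean fertility must be positive")
    return V * F / F_bar


@dataclass
class GenerationRecord:
    """Snapshot of one parental generation after reproduction."""

    t: int
    genotypes: list[str]            # bit-strings, one per individual
    spec_texts: list[str | None]
    F: list[float]
    f: list[float]
    offspring_counts: list[int]     # N_i (initial multinomial draw)
    surviving_counts: list[int]     # survivors among the initial N_i draws
    drawn_total: list[int]          # all draws incl. conditional resampling
    survived_total: list[int]
    parent_index: list[int] = field(default_factory=list)  # parent of individual i
    alpha: list[float | None] = field(default_factory=list)
    pool_survival: list[float | None] = field(default_factory=list)

    @property
    def V_realized(self) -> list[float | None]:
        return [s / d if d > 0 else None
                for s, d in zip(self.survived_total, self.drawn_total)]

    @property
    def V(self) -> list[float | None]:
        """Best available survival estimate: whole-pool validity when logged,
        otherwise the realized draw survival."""
        return [ps if ps is not None else vr
                for ps, vr in zip(self.pool_survival, self.V_realized)]

    @property
    def W(self) -> list[float | None]:
        return [None if v is None else v * F for v, F in zip(self.V, self.F)]

    def to_dict(self) -> dict:
        return {
            "t": self.t, "genotypes": self.genotypes,
            "spec_texts": self.spec_texts, "F": self.F, "f": self.f,
            "offspring_counts": self.offspring_counts,
            "surviving_counts": self.surviving_counts,
            "drawn_total": self.drawn_total,
            "survived_total": self.survived_total,
            "parent_index": self.parent_index,
            "alpha": self.alpha, "pool_survival": self.pool_survival,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationRecord":
        return cls(**d)


def _bits_to_str(g: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in g)


class CodecModel:
    """Full model: genotypes develop through the codec into trained networks."""

    def __init__(self, codec: CodecState, build: BuildConfig, env: Environment,
                 train: TrainConfig, record_pool_survival: bool = True):
        self.codec, self.build, self.env, self.train = codec, build, env, train
        self.record_pool_survival = record_pool_survival

    def make(self, genotype: np.ndarray, rng) -> Individual | None:
        seq = decode(genotype, self.codec)
        report = build_network(seq.text, self.build)
        if report.valid:
            from .netspec import parse_spec
            return Individual(genotype.copy(), parse_spec(seq.text))
        if report.error_kind == "parameter-cap-exceeded":
            from .netspec import parse_spec
            return Individual(genotype.copy(), parse_spec(seq.text), sterile=True)
        return None

    def mature(self, ind: Individual, rng: np.random.Generator) -> None:
        train_individual(ind, self.env, self.train, self.build, rng)

    def fertility(self, ind: Individual) -> float:
        return evaluate_fertility(ind, self.env)

    def pool(self, ind: Individual, rng) -> np.ndarray:
        if ind.sterile:
            return np.tile(ind.genotype, (self.env.n_eval, 1)).astype(np.uint8)
        return self_replicate(ind, self.env)

    def pool_validity(self, pool: np.ndarray) -> float:
        ok = 0
        for g in pool:
            seq = decode(g, self.codec)
            rep = build_network(seq.text, self.build)
            ok += rep.valid or rep.error_kind == "parameter-cap-exceeded"
        return ok / pool.shape[0]


class StubModel:
    """Stub replicators for engine tests: fixed fertility/survival, optional
    bit-flip mutation, no training."""

    def __init__(self, fertility: float | Sequence[float] = 1.0,
                 flip_prob: float = 0.0, survival: float = 1.0,
                 pool_size: int = 50):
        self.fertility_value = fertility
        self.flip_prob, self.survival, self.pool_size = flip_prob, survival, pool_size
        self.record_pool_survival = False
        self._counter = 0

    def _fert(self) -> float:
        if np.isscalar(self.fertility_value):
            return float(self.fertility_value)
        v = self.fertility_value[self._counter % len(self.fertility_value)]
        self._counter += 1
        return float(v)

    def make(self, genotype: np.ndarray, rng) -> StubIndividual | None:
        if self.survival < 1.0 and rng.random() >= self.survival:
            return None
        return StubIndividual(genotype.copy().astype(np.uint8),
                              fertility=self._fert(), flip_prob=self.flip_prob,
                              survival=self.survival)

    def mature(self, ind, rng) -> None:
        pass

    def fertility(self, ind: StubIndividual) -> float:
        ind.F = ind.fertility
        return ind.F

    def pool(self, ind: StubIndividual, rng) -> np.ndarray:
        return ind.replicate(self.pool_size, rng)

    def pool_validity(self, pool: np.ndarray) -> float:
        return self.survival


def produce_next_generation(pools: list[np.ndarray], f: np.ndarray, N: int,
                            model, rng: np.random.Generator):
    """Steps 4-6: multinomial offspring counts, pool draws, survival filter,
    conditional resampling up to the retry budget.

    Returns (offspring individuals, offspring parent indices, counts N_i,
    survivors-of-initial-draw, total drawn, total survived).
    """
    P = len(pools)
    counts = sample_offspring_counts(f, N, rng)
    offspring, parent_idx = [], []
    survivors_initial = np.zeros(P, dtype=int)
    drawn = np.zeros(P, dtype=int)
    survived = np.zeros(P, dtype=int)
    for i in range(P):
        pool = pools[i]
        for _ in range(int(counts[i])):
            g = pool[rng.integers(0, pool.shape[0])]
            drawn[i] += 1
            child = model.make(g, rng)
            if child is not None:
                survivors_initial[i] += 1
                survived[i] += 1
                offspring.append(child)
                parent_idx.append(i)
    budget = RESAMPLE_BUDGET_FACTOR * N
    tries = 0
    while len(offspring) < N:
        if tries >= budget:
            raise ExtinctionError(
                f"resampling budget exhausted with {len(offspring)}/{N} survivors")
        i = int(rng.choice(P, p=f))
        pool = pools[i]
        g = pool[rng.integers(0, pool.shape[0])]
        drawn[i] += 1
        tries += 1
        child = model.make(g, rng)
        if child is not None:
            survived[i] += 1
            offspring.append(child)
            parent_idx.append(i)
    return offspring, parent_idx, counts, survivors_initial, drawn, survived


@dataclass
class RunResult:
    records: list[GenerationRecord]
    final_genotypes: np.ndarray
    seed: int


def _gen_rng(seed: int, t: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, t, tag)))


def individual_rng(seed: int, t: int, index: int) -> np.random.Generator:
    """Training substream for individual ``index`` of generation ``t``."""
    return np.random.default_rng(np.random.SeedSequence((seed, t, _TAG_TRAIN, index)))


def run_experiment(model, ancestors: np.ndarray, N: int, G: int, seed: int,
                   start_t: int = 0) -> RunResult:
    """Run G generations from an ancestor genotype (or genotype matrix).

    With a single ancestor the starting population is isogenic.  Fully
    reproducible from (model config, seed); to resume a checkpointed run,
    pass the checkpoint's genotype matrix as ``ancestors`` and its ``next_t``
    as ``start_t`` -- every stream is re-derived from (seed, t), so the
    continuation matches an uninterrupted run.
    """
    ancestors = np.atleast_2d(np.asarray(ancestors, dtype=np.uint8))
    dev_rng = _gen_rng(seed, start_t, _TAG_INIT)
    population = []
    for i in range(N):
        g = ancestors[i % ancestors.shape[0]]
        child = model.make(g, dev_rng)
        if child is None:
            raise ValueError("an ancestor genotype does not develop validly")
        population.append(child)
    parent_idx = list(range(N))

    records: list[GenerationRecord] = []
    try:
        for t in range(start_t, start_t + G):
            drift_rng = _gen_rng(seed, t, _TAG_DRIFT)
            for i, ind in enumerate(population):
                model.mature(ind, individual_rng(seed, t, i))
            F = np.array([model.fertility(ind) for ind in population])
            f = relative_fertility(F)
            pool_rng = _gen_rng(seed, t, _TAG_POOL)
            pools = [model.pool(ind, pool_rng) for ind in population]
            pool_surv: list[float | None]
            if getattr(model, "record_pool_survival", False):
                pool_surv = [model.pool_validity(p) for p in pools]
            else:
                pool_surv = [None] * len(population)
            (offspring, child_parents, counts, surv_init,
             drawn, survived) = produce_next_generation(pools, f, N, model, drift_rng)
            records.append(GenerationRecord(
                t=t,
                genotypes=[_bits_to_str(ind.genotype) for ind in population],
                spec_texts=[None if ind.spec is None else ind.spec.to_text()
                            for ind in population],
                F=[float(x) for x in F],
                f=[float(x) for x in f],
                offspring_counts=[int(c) for c in counts],
                surviving_counts=[int(s) for s in surv_init],
                drawn_total=[int(d) for d in drawn],
                survived_total=[int(s) for s in survived],
                parent_index=list(parent_idx),
                alpha=[getattr(ind, "spec", None) and ind.spec.alpha
                       for ind in population],
                pool_survival=pool_surv,
            ))
            population, parent_idx = offspring, child_parents
    except ExtinctionError as e:
        raise ExtinctionError(str(e), records) from None
    return RunResult(records, np.stack([ind.genotype for ind in population]),
                     seed)


def select_ancestor(model, candidates: np.ndarray, N: int, G: int,
                    seed: int) -> tuple[int, np.ndarray]:
    """Run each candidate ancestor for G generations and keep the one that
    produced the most viable (surviving) offspring across the run; ties go to
    the lowest index.  A candidate that goes extinct scores 0.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=np.uint8))
    best_idx, best_score = 0, -1
    for idx in range(candidates.shape[0]):
        try:
            result = run_experiment(model, candidates[idx], N, G,
                                    seed=seed + idx)
            score = sum(sum(r.survived_total) for r in result.records)
        except (ExtinctionError, DegeneratePopulationError, ValueError):
            score = 0
        if score > best_score:
            best_idx, best_score = idx, score
    return best_idx, candidates[best_idx]
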