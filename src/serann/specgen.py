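"""Stochastic generator of network specifications.

Architectures are drawn from a first-order Markov chain over layer kinds
(with a dedicated terminal state), and each layer's hyperparameters from a
clipped, rounded ("discrete") normal prior.  The generator supplies both the
corpus used to train the genotype codec and the ancestor pool for evolution
runs.

Only one transition probability is fixed by the model being emulated
(convolutional -> pooling = 0.7, -> convolutional = 0.2, -> fully-connected
= 0.1) together with the fully-connected width prior N(64, 15) clipped to
[8, 128]; every other row and prior here is shipped configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netspec import (
    BuildConfig,
    LayerSpec,
    NetworkSpec,
    Vocabulary,
    build_network,
    tokenize,
)

__all__ = [
    "LayerTransitionModel",
    "HyperparamPrior",
    "GeneratorConfig",
    "GeneratorError",
    "tiny_priors",
    "sample_chain",
    "sample_hyperparameter",
    "sample_architecture",
    "generate_corpus",
    "save_corpus",
    "load_corpus",
]

END = "end"


class GeneratorError(RuntimeError):
    """Raised when the retry budget for a valid architecture is exhausted."""


@dataclass(frozen=True)
class LayerTransitionModel:
    """Markov chain over hidden-layer kinds with an absorbing terminal state.

    ``initial`` is the distribution of the first hidden layer; ``matrix`` maps
    each hidden kind to its next-state distribution over ``states + (end,)``.
    """

    states: tuple[str, ...]
    initial: dict[str, float]
    matrix: dict[str, dict[str, float]]

    def __post_init__(self):
        tol = 1e-9
        rows = {"<initial>": self.initial, **self.matrix}
        for name, row in rows.items():
            total = sum(row.values())
            if abs(total - 1.0) > tol:
                raise ValueError(f"row {name} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"row {name} has a negative probability")
        # terminal state must be reachable from every state
        reach_end = set()
        changed = True
        while changed:
            changed = False
            for s in self.states:
                if s in reach_end:
                    continue
                row = self.matrix[s]
                if row.get(END, 0.0) > 0 or any(
                    row.get(t, 0.0) > 0 and t in reach_end for t in self.states
                ):
                    reach_end.add(s)
                    changed = True
        missing = set(self.states) - reach_end
        if missing:
            raise ValueError(f"terminal state unreachable from {sorted(missing)}")

    @classmethod
    def default(cls) -> "LayerTransitionModel":
        states = ("conv", "pool", "dense", "dropout")
        initial = {"conv": 0.55, "dense": 0.35, "pool": 0.05, "dropout": 0.05}
        matrix = {
            # the conv row follows the published transition probabilities
            "conv": {"pool": 0.7, "conv": 0.2, "dense": 0.1},
            "pool": {"conv": 0.3, "dense": 0.5, "dropout": 0.1, END: 0.1},
            "dense": {"dense": 0.25, "dropout": 0.15, END: 0.6},
            "dropout": {"dense": 0.7, END: 0.3},
        }
        return cls(states, initial, matrix)

    def row_vector(self, state: str | None) -> tuple[list[str], np.ndarray]:
        """Next-state labels and probabilities for ``state`` (None = initial)."""
        row = self.initial if state is None else self.matrix[state]
        labels = list(self.states) + ([END] if state is not None else [])
        probs = np.array([row.get(lbl, 0.0) for lbl in labels])
        return labels, probs


@dataclass(frozen=True)
class HyperparamPrior:
    """Clipped, rounded normal prior for one integer hyperparameter.

    ``step`` coarsens the grid: draws are rounded to the nearest multiple of
    ``step`` (half away from zero), still clipped to [lo, hi].
    """

    mu: float
    sigma: float
    lo: int
    hi: int
    step: int = 1

    def __post_init__(self):
        if not self.lo <= self.mu <= self.hi:
            raise ValueError("prior mean outside clip bounds")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.step < 1:
            raise ValueError("step must be a positive integer")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sample_hyperparameter(prior: HyperparamPrior, rng: np.random.Generator) -> int:
    """One draw: normal(mu, sigma), clipped to [lo, hi], rounded to the
    prior's integer grid."""
    x = prior.mu if prior.sigma == 0 else rng.normal(prior.mu, prior.sigma)
    x = min(max(x, prior.lo), prior.hi)
    v = prior.step * _round_half_away(x / prior.step)
    return min(max(v, prior.lo), prior.hi)


DEFAULT_PRIORS: dict[tuple[str, str], HyperparamPrior] = {
    ("conv", "filters"): HyperparamPrior(16, 8, 4, 32),
    ("conv", "kernel"): HyperparamPrior(3, 1, 1, 5),
    ("pool", "size"): HyperparamPrior(2, 0.5, 2, 3),
    # the published fully-connected width prior
    ("dense", "units"): HyperparamPrior(64, 15, 8, 128),
    ("dropout", "percent"): HyperparamPrior(25, 10, 5, 50),
    # loss weight in units of 1e-4 (alpha = value / 10000)
    ("scaffold", "alpha1e4"): HyperparamPrior(1000, 500, 1, 9999),
}


def tiny_priors() -> dict[tuple[str, str], HyperparamPrior]:
    """Priors for desk-scale runs: small layers on a coarse grid.

    The coarse steps keep the corpus entropy within what a short genotype
    can carry, so the codec converges at desk scale.
    """
    priors = dict(DEFAULT_PRIORS)
    priors[("dense", "units")] = HyperparamPrior(16, 6, 4, 32, step=2)
    priors[("conv", "filters")] = HyperparamPrior(4, 2, 2, 8, step=2)
    priors[("conv", "kernel")] = HyperparamPrior(3, 1, 2, 4)
    priors[("dropout", "percent")] = HyperparamPrior(25, 10, 5, 50, step=5)
    priors[("scaffold", "alpha1e4")] = HyperparamPrior(1000, 300, 100, 3000,
                                                       step=100)
    return priors


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs: chain, priors, budgets, build rules."""

    transitions: LayerTransitionModel = field(default_factory=LayerTransitionModel.default)
    priors: dict[tuple[str, str], HyperparamPrior] = field(
        default_factory=lambda: dict(DEFAULT_PRIORS)
    )
    activation_probs: dict[str, float] = field(
        default_factory=lambda: {"relu": 0.8, "tanh": 0.1, "sigmoid": 0.1}
    )
    token_budget: int = 350
    build: BuildConfig = field(default_factory=BuildConfig)
    retry_cap: int = 100
    max_chain_length: int = 64  # hard safety stop per attempt

    def vocabulary(self) -> Vocabulary:
        return Vocabulary.default()


def sample_chain(
    model: LayerTransitionModel, rng: np.random.Generator, max_length: int = 64
) -> list[str]:
    """Draw one hidden-layer kind sequence from the chain.

    The default initial row has no terminal entry, so chains have length
    >= 1; ``max_length`` is a hard safety stop.
    """
    chain: list[str] = []
    labels, probs = model.row_vector(None)
    state = labels[rng.choice(len(labels), p=probs)]
    while state != END and len(chain) < max_length:
        chain.append(state)
        labels, probs = model.row_vector(state)
        state = labels[rng.choice(len(labels), p=probs)]
    return chain


def _sample_activation(config: GeneratorConfig, rng: np.random.Generator) -> str:
    acts = list(config.activation_probs)
    probs = np.array([config.activation_probs[a] for a in acts])
    return acts[rng.choice(len(acts), p=probs / probs.sum())]


def _chain_to_spec(
    chain: list[str], config: GeneratorConfig, rng: np.random.Generator
) -> NetworkSpec:
    layers = []
    for kind in chain:
        if kind == "conv":
            f = sample_hyperparameter(config.priors[("conv", "filters")], rng)
            ks = sample_hyperparameter(config.priors[("conv", "kernel")], rng)
            layers.append(
                LayerSpec("conv", (("filters", f), ("kernel", ks)),
                          _sample_activation(config, rng))
            )
        elif kind == "pool":
            s = sample_hyperparameter(config.priors[("pool", "size")], rng)
            layers.append(LayerSpec("pool", (("size", s),)))
        elif kind == "dense":
            u = sample_hyperparameter(config.priors[("dense", "units")], rng)
            layers.append(
                LayerSpec("dense", (("units", u),), _sample_activation(config, rng))
            )
        elif kind == "dropout":
            p = sample_hyperparameter(config.priors[("dropout", "percent")], rng)
            layers.append(LayerSpec("dropout", (("percent", p),)))
        else:  # pragma: no cover - chain states are validated
            raise ValueError(f"unknown chain state {kind!r}")
    alpha = sample_hyperparameter(config.priors[("scaffold", "alpha1e4")], rng) / 1e4
    return NetworkSpec(tuple(layers), alpha)


def sample_architecture(
    config: GeneratorConfig, rng: np.random.Generator
) -> NetworkSpec:
    """Draw one spec that builds successfully and fits the token budget.

    Invalid draws (over-budget chains, shape violations, cap excess) are
    resampled up to ``config.retry_cap`` attempts, then a
    :class:`GeneratorError` is raised.
    """
    vocab = config.vocabulary()
    for _ in range(config.retry_cap):
        chain = sample_chain(config.transitions, rng, config.max_chain_length)
        spec = _chain_to_spec(chain, config, rng)
        text = spec.to_text()
        if len(text.split()) > config.token_budget:
            continue
        if not build_network(spec, config.build).valid:
            continue
        # spec must survive the tokenizer round-trip under the shipped vocab
        tokenize(text, vocab, config.token_budget)
        return spec
    raise GeneratorError(f"no valid architecture in {config.retry_cap} attempts")


def generate_corpus(
    n: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Generate ``n`` valid spec texts, reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or GeneratorConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [sample_architecture(config, rng).to_text() for _ in range(n)]


def save_corpus(specs: list[str], path) -> None:
    """Line-delimited archive, one spec per line."""
    with open(path, "w") as fh:
        for s in specs:
            fh.write(s + "\n")


def load_corpus(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
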