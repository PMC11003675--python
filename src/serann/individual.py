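"""A single replicator: a network that classifies images and copies its genotype.

Each individual is built from its spec (the phenotype), with two input
branches -- the image branch, whose hidden layers are the heritable part of
the architecture, and a fixed genotype branch -- merged into a shared head
with two outputs: class probabilities ``y_hat`` (length L) and a replicated
genotype ``g_prime`` (length k, sigmoid units).  Training minimises the
combined loss

    l = alpha * l_X(y, y_hat) + (1 - alpha) * l_g(g, g_prime)

where ``l_X`` is categorical cross entropy, ``l_g`` the mean squared error
over genotype bits, and the weight ``alpha`` is declared in the spec itself,
so it is heritable.  Network weights are Glorot-initialised and never
inherited; only the architecture is.

Replication output depends on the paired image input (the branches share the
head), so offspring genotypes are not independent of the classification
input -- unexpected image inputs can act as mutagens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2D, softmax
from .netspec import BuildConfig, NetworkSpec

__all__ = [
    "Individual", "StubIndividual", "TrainConfig", "Environment",
    "SerannNet", "combined_loss", "train_individual", "evaluate_fertility",
    "self_replicate", "predict",
]

EPS = 1e-12


def combined_loss(y, y_hat, g, g_prime, alpha: float) -> float:
    """alpha * cross-entropy + (1 - alpha) * genotype MSE.

    Accepts single examples (1-D) or batches (2-D, averaged over rows).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    g = np.atleast_2d(np.asarray(g, dtype=float))
    g_prime = np.atleast_2d(np.asarray(g_prime, dtype=float))
    l_x = -(y * np.log(np.clip(y_hat, EPS, None))).sum(axis=1)
    l_g = ((g - g_prime) ** 2).mean(axis=1)
    return float((alpha * l_x + (1.0 - alpha) * l_g).mean())


@dataclass(frozen=True)
class TrainConfig:
    """Per-individual training settings (five epochs in the full-scale setup)."""

    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 2e-3


@dataclass
class Environment:
    """Shared per-generation data: classification sets and the genotype pool.

    ``genotype_pool`` holds corpus genotypes used for the replication task
    during training; the evaluation set is fixed and shared by all
    individuals of a generation.
    """

    train_images: np.ndarray      # (n_train, m, n)
    train_labels: np.ndarray      # (n_train, L) one-hot
    eval_images: np.ndarray       # (n_eval, m, n)
    eval_labels: np.ndarray       # (n_eval, L) one-hot
    genotype_pool: np.ndarray     # (n_pool, k) binary

    @property
    def n_eval(self) -> int:
        return self.eval_images.shape[0]


class SerannNet:
    """The two-branch network built from a spec."""

    def __init__(self, spec: NetworkSpec, build: BuildConfig,
                 rng: np.random.Generator):
        self.spec, self.build = spec, build
        m, n = build.image_shape
        shape: tuple | int = (m, n, 1)
        branch: list[_nn.Layer] = []
        for lay in spec.layers:
            if lay.kind == "conv":
                r, c, ch = shape
                branch.append(Conv2D(ch, lay.get("filters"), lay.get("kernel"),
                                     lay.activation, rng))
                shape = (r, c, lay.get("filters"))
            elif lay.kind == "pool":
                r, c, ch = shape
                s = lay.get("size")
                branch.append(MaxPool2D(s))
                shape = (r // s, c // s, ch)
            elif lay.kind == "dense":
                if isinstance(shape, tuple):
                    branch.append(Flatten())
                    shape = shape[0] * shape[1] * shape[2]
                branch.append(Dense(shape, lay.get("units"), lay.activation, rng))
                shape = lay.get("units")
            elif lay.kind == "dropout":
                branch.append(Dropout(lay.get("percent") / 100.0, rng))
        if isinstance(shape, tuple):
            branch.append(Flatten())
            shape = shape[0] * shape[1] * shape[2]
        self.image_branch = _nn.Sequential(branch)
        self.gen_branch = Dense(build.genotype_length, build.genotype_units,
                                "relu", rng)
        merged = shape + build.genotype_units
        self.head = Dense(merged, build.head_units, "relu", rng)
        self.class_out = Dense(build.head_units, build.n_classes, None, rng)
        self.repl_out = Dense(build.head_units, build.genotype_length,
                              "sigmoid", rng)
        self._flat_dim = shape

    def _layers(self):
        return (self.image_branch.layers
                + [self.gen_branch, self.head, self.class_out, self.repl_out])

    def all_params(self):
        return [(p, g) for lay in self._layers()
                for p, g in zip(lay.params, lay.grads)]

    def zero_grad(self):
        for lay in self._layers():
            lay.zero_grad()

    def forward(self, X: np.ndarray, G: np.ndarray, train=False):
        """Return (class probabilities, replicated genotype in (0,1))."""
        x = X[..., None] if X.ndim == 3 else X
        h_img = self.image_branch.forward(x, train=train)
        h_gen = self.gen_branch.forward(G, train=train)
        merged = np.concatenate([h_img, h_gen], axis=1)
        h = self.head.forward(merged, train=train)
        logits = self.class_out.forward(h, train=train)
        g_prime = self.repl_out.forward(h, train=train)
        return softmax(logits), g_prime

    def backward(self, dlogits: np.ndarray, dg_prime_pre: np.ndarray):
        """Backprop given d(loss)/d(class logits) and d(loss)/d(g_prime)."""
        dh = self.class_out.backward(dlogits) + self.repl_out.backward(dg_prime_pre)
        dmerged = self.head.backward(dh)
        dimg, dgen = dmerged[:, :self._flat_dim], dmerged[:, self._flat_dim:]
        self.gen_branch.backward(dgen)
        self.image_branch.backward(dimg)


@dataclass
class Individual:
    """Genotype + phenotype + measured fitness components.

    ``W = V * F`` whenever both are set.  ``sterile`` marks individuals over
    the parameter cap: alive but with fertility forced to 0.
    """

    genotype: np.ndarray
    spec: NetworkSpec | None = None
    sterile: bool = False
    F: float | None = None
    V: float | None = None
    net: SerannNet | None = None
    loss_trace: list[float] = field(default_factory=list)

    @property
    def alpha(self) -> float | None:
        return None if self.spec is None else self.spec.alpha

    @property
    def W(self) -> float | None:
        if self.F is None or self.V is None:
            return None
        return self.V * self.F


def train_individual(ind: Individual, env: Environment,
                     config: TrainConfig, build: BuildConfig,
                     rng: np.random.Generator) -> Individual:
    """Initialise and train an individual's network on the dual task.

    Each training example pairs an image with a genotype drawn from the
    corpus genotype pool; batches are joint (one combined loss).  Seeded:
    the same rng stream gives identical final metrics.
    """
    if ind.sterile:
        return ind
    net = SerannNet(ind.spec, build, rng)
    alpha = ind.spec.alpha
    X, Y = env.train_images, env.train_labels
    n = X.shape[0]
    k = build.genotype_length
    opt = Adam(net.all_params(), lr=config.learning_rate)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        gsel = env.genotype_pool[rng.integers(0, env.genotype_pool.shape[0], n)]
        total, seen = 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, yb, gb = X[idx], Y[idx], gsel[s:s + config.batch_size].astype(float)
            B = xb.shape[0]
            y_hat, g_prime = net.forward(xb, gb, train=True)
            l_x = -(yb * np.log(np.clip(y_hat, EPS, None))).sum() / B
            l_g = ((gb - g_prime) ** 2).mean()
            total += (alpha * l_x + (1 - alpha) * l_g) * B
            seen += B
            dlogits = alpha * (y_hat - yb) / B
            # repl_out has a sigmoid activation; its backward applies the
            # sigmoid jacobian, so pass d(loss)/d(g_prime) here
            dgp = (1 - alpha) * 2.0 * (g_prime - gb) / (k * B)
            net.zero_grad()
            net.backward(dlogits, dgp)
            opt.step()
        trace.append(total / seen)
    ind.net = net
    ind.loss_trace = trace
    return ind


def predict(ind: Individual, images: np.ndarray,
            genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if ind.net is None:
        raise ValueError("individual is not trained")
    return ind.net.forward(images, np.asarray(genotypes, dtype=float))


def evaluate_fertility(ind: Individual, env: Environment) -> float:
    """Classification accuracy on the shared evaluation set (own genotype
    paired with every image); order-invariant by construction."""
    if ind.sterile:
        ind.F = 0.0
        return 0.0
    G = np.tile(ind.genotype.astype(float), (env.n_eval, 1))
    y_hat, _ = predict(ind, env.eval_images, G)
    correct = (y_hat.argmax(axis=1) == env.eval_labels.argmax(axis=1)).sum()
    ind.F = float(correct) / env.n_eval
    return ind.F


def self_replicate(ind: Individual, env: Environment) -> np.ndarray:
    """Produce the potential-offspring genotype pool: one hardened k-bit copy
    per evaluation image."""
    G = np.tile(ind.genotype.astype(float), (env.n_eval, 1))
    _, g_prime = predict(ind, env.eval_images, G)
    return (g_prime > 0.5).astype(np.uint8)


@dataclass
class StubIndividual:
    """Non-training stand-in for engine and estimator tests.

    Fertility is fixed; replication flips each bit independently with
    probability ``flip_prob``; offspring viability is Bernoulli with
    probability ``survival``.
    """

    genotype: np.ndarray
    fertility: float = 1.0
    flip_prob: float = 0.0
    survival: float = 1.0
    sterile: bool = False
    F: float | None = None
    V: float | None = None
    spec: NetworkSpec | None = None

    @property
    def W(self) -> float | None:
        if self.F is None or self.V is None:
            return None
        return self.V * self.F

    def replicate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        g = np.tile(self.genotype, (n, 1))
        if self.flip_prob > 0:
            flips = rng.random(g.shape) < self.flip_prob
            g = g ^ flips
        return g.astype(np.uint8)
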