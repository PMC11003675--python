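"""Run configuration: one object tying together every component's settings.

``RunConfig`` mirrors the experimental knobs of the full-scale setup
(population size N, generations G, genotype length k, token budget d, five
training epochs, a 2,000,000 trainable-parameter cap, a 350-token source
budget) and derives the per-component config objects from them.  Two presets
are shipped: :func:`main_config` at the published scale and
:func:`tiny_config`, a desk-scale configuration that runs end to end on one
CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .datasets import SyntheticImageConfig
from .individual import TrainConfig
from .netspec import BuildConfig
from .riboae import CodecConfig
from .specgen import GeneratorConfig

__all__ = ["RunConfig", "main_config", "tiny_config",
           "save_run_config", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Experiment-level configuration.

    All sizes must be positive; ``parameter_cap`` defaults to 2,000,000 and
    ``token_cap`` to 350.
    """

    N: int = 1000
    G: int = 6000
    k: int = 100
    d: int = 350
    epochs: int = 5
    parameter_cap: int = 2_000_000
    token_cap: int = 350
    image_shape: tuple[int, int] = (28, 28)
    n_classes: int = 10
    train_size: int = 57_000
    eval_size: int = 3_000
    corpus_size: int = 1_000_000
    codec_epochs: int = 150
    train_lr: float = 1e-3
    train_batch: int = 32
    generator_preset: str = "default"  # "default" | "tiny"
    seed: int = 0

    def __post_init__(self):
        for name in ("N", "G", "k", "d", "epochs", "parameter_cap",
                     "token_cap", "n_classes", "train_size", "eval_size",
                     "corpus_size", "codec_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def build_config(self) -> BuildConfig:
        return BuildConfig(image_shape=self.image_shape,
                           n_classes=self.n_classes,
                           genotype_length=self.k,
                           parameter_cap=self.parameter_cap)

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.train_batch,
                           learning_rate=self.train_lr)

    def generator_config(self) -> GeneratorConfig:
        from .specgen import tiny_priors
        kwargs = {}
        if self.generator_preset == "tiny":
            kwargs["priors"] = tiny_priors()
        return GeneratorConfig(token_budget=self.token_cap,
                               build=self.build_config(), **kwargs)

    def codec_config(self) -> CodecConfig:
        return CodecConfig(d=self.d, k=self.k, epochs=self.codec_epochs,
                           seed=self.seed)

    def image_config(self) -> SyntheticImageConfig:
        return SyntheticImageConfig(n_classes=self.n_classes,
                                    image_shape=self.image_shape,
                                    train_size=self.train_size,
                                    eval_size=self.eval_size,
                                    seed=self.seed)


def main_config(seed: int = 0) -> RunConfig:
    """The full-scale configuration (not intended for desk hardware)."""
    return RunConfig(seed=seed)


def tiny_config(seed: int = 0) -> RunConfig:
    """Desk-scale preset: a complete run on one CPU in minutes.

    Sizes were chosen once for feasibility: 16 individuals, 10 generations,
    24-bit genotypes, 12x12 five-class glyphs, a 64-token budget, small-layer
    generator priors, and a 200-spec codec corpus.  Per-individual training
    uses more epochs and a higher learning rate than the full-scale setup to
    compensate for the small training set (20 epochs over 240 examples).
    """
    return RunConfig(N=16, G=10, k=24, d=64, token_cap=64, epochs=20,
                     image_shape=(12, 12), n_classes=5,
                     train_size=240, eval_size=60,
                     corpus_size=200, codec_epochs=300,
                     train_lr=0.01, train_batch=8,
                     generator_preset="tiny", seed=seed)


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    data["image_shape"] = tuple(data["image_shape"])
    return RunConfig(**data)
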