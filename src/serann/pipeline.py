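"""End-to-end orchestration: corpus -> codec -> environment -> evolution.

One call runs the whole experiment a RunConfig describes.  Used by the CLI
and the end-to-end tests; every stage draws its randomness from the run
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .datasets import make_synthetic_images
from .evolution import CodecModel, RunResult, run_experiment
from .individual import Environment
from .netspec import build_network
from .riboae import CodecState, decode, encode, train_codec
from .specgen import generate_corpus

__all__ = ["ExperimentArtifacts", "build_model", "pick_viable_ancestor",
           "run_full_experiment"]


@dataclass
class ExperimentArtifacts:
    codec: CodecState
    model: CodecModel
    ancestor: np.ndarray
    result: RunResult
    corpus: list[str]


def build_model(cfg: RunConfig, codec: CodecState, corpus: list[str],
                pool_size: int = 500) -> CodecModel:
    """Assemble the environment (images + genotype pool) and codec model."""
    X, Y, eX, eY = make_synthetic_images(cfg.image_config())
    pool_specs = corpus[: min(len(corpus), pool_size)]
    pool = np.stack([encode(s, codec) for s in pool_specs])
    env = Environment(X, Y, eX, eY, pool)
    return CodecModel(codec, cfg.build_config(), env, cfg.train_config())


def pick_viable_ancestor(codec: CodecState, corpus: list[str],
                         build_cfg) -> np.ndarray:
    """First corpus spec whose encoding decodes to a buildable spec,
    preferring codec fixed points (decode(encode(s)) == s)."""
    fallback = None
    for s in corpus:
        g = encode(s, codec)
        s2 = decode(g, codec).text
        if not build_network(s2, build_cfg).valid:
            continue
        if s2 == s:
            return g
        if fallback is None:
            fallback = g
    if fallback is None:
        raise RuntimeError("no corpus spec decodes to a buildable phenotype")
    return fallback


def run_full_experiment(cfg: RunConfig, seed: int | None = None,
                        codec: CodecState | None = None) -> ExperimentArtifacts:
    """Corpus generation, codec training, ancestor selection, and the
    Wright-Fisher run, all driven by one RunConfig."""
    seed = cfg.seed if seed is None else seed
    corpus = generate_corpus(cfg.corpus_size, cfg.generator_config(),
                             rng=seed)
    if codec is None:
        ccfg = cfg.codec_config()
        codec = train_codec(corpus, ccfg)
    model = build_model(cfg, codec, corpus)
    ancestor = pick_viable_ancestor(codec, corpus, cfg.build_config())
    result = run_experiment(model, ancestor, cfg.N, cfg.G, seed)
    return ExperimentArtifacts(codec, model, ancestor, result, corpus)
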