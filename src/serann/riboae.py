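"""The genotype codec: a "ribosomal" autoencoder over spec token sequences.

The encoder maps a token sequence (length ``d``, vocabulary size ``r``) to a
``k``-bit binary genotype (reverse translation); the decoder maps a genotype
back to a token sequence (translation).  During training the decoder input is
a stochastic relaxation of the encoder output: each encoder unit ``phi_i`` in
[0, 1] is treated as a Bernoulli parameter, and a reparameterised sample

    z_i = log phi_i + log u_i - log(1 - u_i),   u_i ~ U(0, 1)
    soft_g_i = 1 / (1 + exp(-z_i))

is fed to the decoder, so reconstruction error can backpropagate through the
sampling step.  This noise is what makes the learned code robust to bit
flips.  At inference the relaxation is dropped and bits are hardened at 0.5
(``phi_i > 0.5 -> 1``), so encoding is deterministic.

Two relaxation forms are provided (see docs/methods.md for the full
rationale).  ``concrete_relax`` is the log-phi form written out above; it
has the property that a saturated unit (phi = 1) still emits a uniform
sample, which makes the training channel asymmetric and, in our desk-scale
experiments, collapses the latent code.  The default used by training is
the standard temperature-1 binary Concrete,

    z_i = logit(phi_i) + logit(u_i),    soft_g_i = logistic(z_i),

whose samples concentrate near 0 and 1 as the encoder saturates.  There is
no temperature annealing and no KL/prior term in the loss: the loss is the
plain negative log-likelihood of the input sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .netspec import TokenSequence, Vocabulary, detokenize, tokenize
from ._nn import Adam, Conv1D, Dense, Embedding, Flatten, Sequential, softmax

__all__ = [
    "CodecConfig", "CodecState", "RelaxationSample", "TrainingError",
    "concrete_relax", "binary_concrete", "harden", "encode", "decode",
    "token_posterior",
    "reconstruction_nll", "train_codec", "save_codec", "load_codec",
    "single_bit_survival",
]

#: clamp for log(0) in the NLL and for 1/phi in the relaxation gradient
NLL_EPS = 1e-12
PHI_EPS = 1e-6


class TrainingError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class CodecConfig:
    """Architecture and training hyperparameters of the codec.

    ``d`` is the padded sequence length, ``k`` the genotype length.  The
    encoder is an embedding, three strided 1-D convolutions and a dense head
    ending in a sigmoid; the decoder is one 1-D convolution and a dense head
    emitting ``d x r`` token scores.  Layer widths are shipped defaults sized
    so small configurations train on one CPU in seconds to minutes.
    """

    d: int = 350
    k: int = 100
    embed_width: int = 16
    conv_channels: tuple[int, int, int] = (32, 32, 32)
    conv_kernels: tuple[int, int, int] = (5, 5, 3)
    conv_strides: tuple[int, int, int] = (2, 2, 2)
    conv_activation: str = "tanh"
    decoder_channels: int = 32
    decoder_kernel: int = 5
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 3e-3
    lr_decay: bool = True  # step to lr/3 at 60% and lr/10 at 85% of epochs
    relaxation: str = "concrete"  # "concrete" (logit form) | "printed" (log form)
    seed: int = 0


@dataclass
class CodecState:
    """Trained codec: parameters plus training metadata."""

    config: CodecConfig
    vocab: Vocabulary
    encoder: Sequential
    decoder: Sequential
    loss_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def d(self) -> int:
        return self.config.d


@dataclass(frozen=True)
class RelaxationSample:
    """One draw of the relaxed-Bernoulli sampling step, kept for inspection."""

    phi: np.ndarray
    u: np.ndarray
    z: np.ndarray
    soft_g: np.ndarray


def concrete_relax(phi: np.ndarray, u: np.ndarray) -> np.ndarray:
    """logistic(log phi + log u - log(1-u)), elementwise; phi_i = 0 maps to 0."""
    phi = np.asarray(phi, dtype=float)
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(phi)
    pos = phi > 0
    z = np.log(phi[pos]) + np.log(u[pos]) - np.log1p(-u[pos])
    with np.errstate(over="ignore"):  # exp overflow saturates to 0 correctly
        out[pos] = 1.0 / (1.0 + np.exp(-z))
    return out


def binary_concrete(phi: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Standard temperature-1 binary Concrete: logistic(logit phi + logit u).

    Unlike :func:`concrete_relax`, samples concentrate near 0/1 as phi
    saturates; this is the form training uses by default.
    """
    phi = np.clip(np.asarray(phi, dtype=float), PHI_EPS, 1.0 - PHI_EPS)
    u = np.asarray(u, dtype=float)
    z = np.log(phi) - np.log1p(-phi) + np.log(u) - np.log1p(-u)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def relax_sample(phi: np.ndarray, rng: np.random.Generator) -> RelaxationSample:
    u = rng.uniform(0.0, 1.0, size=phi.shape)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    soft = concrete_relax(phi, u)
    with np.errstate(divide="ignore"):
        z = np.log(np.maximum(phi, 0)) + np.log(u) - np.log1p(-u)
    return RelaxationSample(phi, u, z, soft)


def harden(phi: np.ndarray) -> np.ndarray:
    """Round Bernoulli parameters to bits: 1 iff phi > 0.5 (boundary -> 0)."""
    return (np.asarray(phi) > 0.5).astype(np.uint8)


def _build_encoder(cfg: CodecConfig, r: int, rng: np.random.Generator) -> Sequential:
    layers: list = [Embedding(r, cfg.embed_width, rng)]
    c_in, T = cfg.embed_width, cfg.d
    for ch, ks, st in zip(cfg.conv_channels, cfg.conv_kernels, cfg.conv_strides):
        layers.append(Conv1D(c_in, ch, ks, st, cfg.conv_activation, rng))
        c_in, T = ch, -(-T // st)
    layers.append(Flatten())
    layers.append(Dense(T * c_in, cfg.k, "sigmoid", rng))
    return Sequential(layers)


class _BitFeatures(_nn.Layer):
    """Decoder input stage: (B, k) -> (B, k, 2) raw and log-amplitude channels.

    Relaxed samples of a 0-parameter bit sit around exp(log phi + logit u),
    i.e. orders of magnitude below those of a 1-parameter bit, so the two
    classes are linearly separable on a log scale; exposing that scale as a
    fixed feature lets the first convolution read the bit directly.  Hardened
    bits at inference map to the extremes of the same features.
    """

    _EPS = 1e-9
    _FLOOR = -25.0
    _SCALE = 10.0

    def forward(self, x, train=False):
        self._x = x
        raw = np.log(x + self._EPS)
        self._active = (raw > self._FLOOR) & (raw < 0.0)
        return np.stack([x, np.clip(raw, self._FLOOR, 0.0) / self._SCALE],
                        axis=-1)

    def backward(self, grad):
        return grad[..., 0] + grad[..., 1] * self._active / (
            self._SCALE * (self._x + self._EPS))


def _build_decoder(cfg: CodecConfig, r: int, rng: np.random.Generator) -> Sequential:
    layers = [
        _BitFeatures(),
        Conv1D(2, cfg.decoder_channels, cfg.decoder_kernel, 1,
               cfg.conv_activation, rng),
        Flatten(),
        Dense(cfg.k * cfg.decoder_channels, cfg.d * r, None, rng),
    ]
    return Sequential(layers)


def _as_ids(seq, vocab: Vocabulary, d: int) -> np.ndarray:
    if isinstance(seq, TokenSequence):
        return np.asarray(seq.ids, dtype=np.int64)
    if isinstance(seq, str):
        return np.asarray(tokenize(seq, vocab, d).ids, dtype=np.int64)
    return np.asarray(seq, dtype=np.int64)


def encode(seq, state: CodecState) -> np.ndarray:
    """Deterministically encode one sequence to a hardened k-bit genotype."""
    ids = _as_ids(seq, state.vocab, state.d)
    if ids.shape != (state.d,):
        raise ValueError(f"sequence length {ids.shape} != d={state.d}")
    phi = state.encoder.forward(ids[None, :])
    return harden(phi[0])


def encode_batch(ids: np.ndarray, state: CodecState) -> np.ndarray:
    return harden(state.encoder.forward(np.asarray(ids, dtype=np.int64)))


def token_posterior(g: np.ndarray, state: CodecState) -> tuple[np.ndarray, np.ndarray]:
    """Decoder scores (d, r) and their per-position softmax probabilities."""
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    if single:
        g = g[None, :]
    r = state.vocab.size
    scores = state.decoder.forward(g).reshape(g.shape[0], state.d, r)
    probs = softmax(scores, axis=-1)
    return (scores[0], probs[0]) if single else (scores, probs)


def decode(g: np.ndarray, state: CodecState) -> TokenSequence:
    """Translate a genotype: argmax token per position, truncated at padding."""
    _, probs = token_posterior(g, state)
    ids = probs.argmax(axis=-1)
    text = detokenize(ids, state.vocab)
    # re-canonicalise: ids after the first padding token are replaced by padding
    return tokenize(text, state.vocab, state.d)


def reconstruction_nll(true_ids, probs: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Negative log-likelihood of the sequence under the token posterior.

    Padding positions are included by default; pass a boolean ``mask`` to
    restrict to content positions.
    """
    ids = np.asarray(true_ids if not isinstance(true_ids, TokenSequence)
                     else true_ids.ids, dtype=np.int64)
    p = probs[np.arange(len(ids)), ids]
    logp = np.log(np.clip(p, NLL_EPS, None))
    if mask is not None:
        logp = logp[np.asarray(mask, dtype=bool)]
    return float(-logp.sum())


def train_codec(corpus: list[str], config: CodecConfig,
                vocab: Vocabulary | None = None,
                rng: np.random.Generator | None = None) -> CodecState:
    """Train the codec on a corpus of spec texts.

    Per batch: encode to phi, draw the relaxed Bernoulli sample, decode, and
    minimise the sequence NLL with Adam.  Fully seeded; two runs with the
    same config and corpus produce identical loss traces.
    """
    vocab = vocab or Vocabulary.default()
    rng = rng or np.random.default_rng(config.seed)
    r = vocab.size
    ids = np.stack([
        np.asarray(tokenize(s, vocab, config.d).ids, dtype=np.int64)
        for s in corpus
    ])
    n = ids.shape[0]
    encoder = _build_encoder(config, r, rng)
    decoder = _build_decoder(config, r, rng)
    opt = Adam(encoder.all_params() + decoder.all_params(),
               lr=config.learning_rate)
    onehot_eye = np.eye(r)
    trace: list[float] = []
    for epoch in range(config.epochs):
        if config.lr_decay:
            frac = epoch / max(config.epochs, 1)
            opt.lr = config.learning_rate * (
                1.0 if frac < 0.6 else (1 / 3 if frac < 0.85 else 0.1))
        order = rng.permutation(n)
        epoch_nll, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = ids[order[start:start + config.batch_size]]
            B = batch.shape[0]
            phi = encoder.forward(batch, train=True)
            u = np.clip(rng.uniform(size=phi.shape), 1e-12, 1 - 1e-12)
            if config.relaxation == "concrete":
                soft = binary_concrete(phi, u)
            elif config.relaxation == "printed":
                soft = concrete_relax(phi, u)
            else:
                raise ValueError(f"unknown relaxation {config.relaxation!r}")
            scores = decoder.forward(soft, train=True).reshape(B, config.d, r)
            probs = softmax(scores, axis=-1)
            pt = np.take_along_axis(probs, batch[..., None], axis=-1)[..., 0]
            nll = -np.log(np.clip(pt, NLL_EPS, None)).sum()
            if not np.isfinite(nll):
                raise TrainingError("non-finite training loss")
            epoch_nll += float(nll)
            seen += B
            dscores = (probs - onehot_eye[batch]) / B
            encoder.zero_grad()
            decoder.zero_grad()
            dsoft = decoder.backward(dscores.reshape(B, -1))
            dz = dsoft * soft * (1.0 - soft)
            if config.relaxation == "concrete":
                phic = np.clip(phi, PHI_EPS, 1.0 - PHI_EPS)
                dphi = dz / (phic * (1.0 - phic))
            else:
                dphi = dz / np.maximum(phi, PHI_EPS)
            encoder.backward(dphi)
            opt.step()
        trace.append(epoch_nll / seen)
    return CodecState(config, vocab, encoder, decoder, trace)


def save_codec(state: CodecState, path) -> None:
    """Portable binary container (npz) with an embedded config + vocab digest."""
    meta = {
        "config": asdict(state.config),
        "vocab_tokens": list(state.vocab.tokens),
        "vocab_digest": state.vocab.digest(),
        "loss_trace": state.loss_trace,
    }
    arrays = {}
    for i, (p, _) in enumerate(state.encoder.all_params()):
        arrays[f"enc_{i}"] = p
    for i, (p, _) in enumerate(state.decoder.all_params()):
        arrays[f"dec_{i}"] = p
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_codec(path, vocab: Vocabulary | None = None) -> CodecState:
    """Load a saved codec; refuses to load under a mismatched vocabulary."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        stored_vocab = Vocabulary(tuple(meta["vocab_tokens"]))
        if vocab is not None and vocab.digest() != meta["vocab_digest"]:
            raise ValueError("codec was trained under a different vocabulary")
        cfg_dict = meta["config"]
        for key in ("conv_channels", "conv_kernels", "conv_strides"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = CodecConfig(**cfg_dict)
        rng = np.random.default_rng(0)
        encoder = _build_encoder(cfg, stored_vocab.size, rng)
        decoder = _build_decoder(cfg, stored_vocab.size, rng)
        for i, (p, _) in enumerate(encoder.all_params()):
            p[...] = npz[f"enc_{i}"]
        for i, (p, _) in enumerate(decoder.all_params()):
            p[...] = npz[f"dec_{i}"]
    return CodecState(cfg, stored_vocab, encoder, decoder, meta["loss_trace"])


def single_bit_survival(state: CodecState, genotypes: np.ndarray,
                        build_config=None) -> float:
    """Fraction of single-bit mutants that decode to buildable specs.

    A smoothness probe of the learned code: for each genotype, every one of
    its k single-bit flips is decoded and built; the returned value is the
    overall buildable fraction, in [0, 1].
    """
    from .netspec import build_network

    genotypes = np.atleast_2d(np.asarray(genotypes))
    n_ok = n_tot = 0
    for g in genotypes:
        for site in range(state.k):
            mut = g.copy()
            mut[site] ^= 1
            seq = decode(mut, state)
            n_ok += build_network(seq.text, build_config).valid
            n_tot += 1
    return n_ok / n_tot
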