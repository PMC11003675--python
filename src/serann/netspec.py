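"""Network-specification dialect: the phenotype of a self-replicating network.

A phenotype is a short text in a constrained layer-description language.  Every
spec carries a fixed scaffold -- an input marker, a merge marker (where the
image branch joins the genotype branch), a ``loss_weight`` declaration and an
output marker -- and a variable chain of hidden layers in between.  Only the
hidden chain and the loss weight differ between individuals, so only they are
effectively heritable.

The dialect is deliberately small: one token per lexeme, no significant
whitespace, numbers spelled digit by digit.  A spec either parses and builds
into a well-shaped network (and reports its closed-form trainable-parameter
count), or fails with a typed error; "execution error" in the underlying
model maps to a parse/build failure here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Vocabulary",
    "TokenSequence",
    "LayerSpec",
    "NetworkSpec",
    "BuildConfig",
    "BuildReport",
    "SpecError",
    "UnknownTokenError",
    "SpecLengthError",
    "SpecParseError",
    "ScaffoldError",
    "tokenize",
    "detokenize",
    "parse_spec",
    "build_network",
    "ALPHA_DECIMALS",
]

#: fixed decimal precision of the loss-weight literal (finer than the smallest
#: heritable shift we care about, which is on the order of 2e-3)
ALPHA_DECIMALS = 4

PAD_TOKEN = "<pad>"

_DEFAULT_TOKENS = (
    [PAD_TOKEN, ";", ".", ","]
    + [str(i) for i in range(10)]
    + ["input", "merge", "output", "loss_weight"]
    + ["conv", "pool", "dense", "dropout"]
    + ["relu", "tanh", "sigmoid"]
)

ACTIVATIONS = ("relu", "tanh", "sigmoid")

#: legal hyperparameter ranges of the dialect (inclusive)
HYPERPARAM_RANGES = {
    ("conv", "filters"): (1, 64),
    ("conv", "kernel"): (1, 7),
    ("pool", "size"): (2, 4),
    ("dense", "units"): (1, 1024),
    ("dropout", "percent"): (1, 90),
}


class SpecError(ValueError):
    """Base class for dialect errors."""


class UnknownTokenError(SpecError):
    """A lexeme is not in the vocabulary."""


class SpecLengthError(SpecError):
    """Content token count exceeds the budget d."""


class SpecParseError(SpecError):
    """The token stream does not follow the dialect grammar."""


class ScaffoldError(SpecError):
    """input/merge/loss_weight/output missing, duplicated, or out of order."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token set; position in ``tokens`` is the integer id."""

    tokens: tuple[str, ...]
    pad_token: str = PAD_TOKEN

    def __post_init__(self):
        if len(self.tokens) < 2:
            raise ValueError("vocabulary needs at least 2 tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be distinct")
        if sum(t == self.pad_token for t in self.tokens) != 1:
            raise ValueError("vocabulary must contain the padding token exactly once")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    @classmethod
    def default(cls) -> "Vocabulary":
        return cls(tuple(_DEFAULT_TOKENS))

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self._index[self.pad_token]

    def id_of(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise UnknownTokenError(f"token {token!r} not in vocabulary") from None

    def token_of(self, idx: int) -> str:
        return self.tokens[idx]

    def digest(self) -> str:
        """Stable fingerprint used to refuse codec/vocabulary mismatches."""
        h = hashlib.sha256("\n".join(self.tokens).encode())
        return h.hexdigest()[:16]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def from_file(cls, path) -> "Vocabulary":
        with open(path) as fh:
            toks = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        return cls(tuple(toks))


@dataclass(frozen=True)
class TokenSequence:
    """A spec as integer ids padded to exactly ``d`` entries."""

    ids: tuple[int, ...]
    text: str

    @property
    def length(self) -> int:
        return len(self.ids)

    def content_length(self, vocab: Vocabulary) -> int:
        pad = vocab.pad_id
        n = len(self.ids)
        while n > 0 and self.ids[n - 1] == pad:
            n -= 1
        return n


def tokenize(text: str, vocab: Vocabulary, d: int) -> TokenSequence:
    """Segment ``text`` into vocabulary ids and pad to exactly ``d`` entries.

    Raises :class:`UnknownTokenError` for out-of-vocabulary lexemes and
    :class:`SpecLengthError` when the content exceeds the budget.
    """
    lexemes = text.split()
    if len(lexemes) > d:
        raise SpecLengthError(f"content has {len(lexemes)} tokens, budget is {d}")
    ids = [vocab.id_of(t) for t in lexemes]
    ids.extend([vocab.pad_id] * (d - len(ids)))
    return TokenSequence(tuple(ids), " ".join(lexemes))


def detokenize(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize`; reading stops at the first padding id."""
    out = []
    pad = vocab.pad_id
    for i in ids:
        if i == pad:
            break
        out.append(vocab.token_of(int(i)))
    return " ".join(out)


@dataclass(frozen=True)
class LayerSpec:
    """One hidden layer: ``kind`` plus its hyperparameters."""

    kind: str  # conv | pool | dense | dropout
    params: tuple[tuple[str, int], ...] = ()
    activation: str | None = None

    def get(self, name: str) -> int:
        return dict(self.params)[name]


@dataclass(frozen=True)
class NetworkSpec:
    """Parsed phenotype: hidden-layer chain plus the heritable loss weight."""

    layers: tuple[LayerSpec, ...]
    alpha: float  # classification-vs-replication loss weight, in [0, 1]

    def to_text(self) -> str:
        parts = ["input", ";"]
        for lay in self.layers:
            parts.append(lay.kind)
            for p, (_, v) in enumerate(lay.params):
                if p > 0:
                    parts.append(",")  # separator between numeric lexemes
                parts.extend(list(str(v)))
            if lay.activation is not None:
                parts.append(lay.activation)
            parts.append(";")
        parts += ["merge", ";", "loss_weight"]
        parts.extend(list(format_alpha(self.alpha)))
        parts += [";", "output", ";"]
        return " ".join(parts)


def format_alpha(alpha: float) -> str:
    """Render alpha with the dialect's fixed decimal precision."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return f"{alpha:.{ALPHA_DECIMALS}f}"


class _Cursor:
    def __init__(self, toks: list[str]):
        self.toks = toks
        self.pos = 0

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        if self.pos >= len(self.toks):
            raise SpecParseError("unexpected end of spec")
        t = self.toks[self.pos]
        self.pos += 1
        return t

    def expect(self, tok: str) -> None:
        got = self.take()
        if got != tok:
            raise SpecParseError(f"expected {tok!r}, got {got!r}")


def _read_int(cur: _Cursor) -> int:
    digits = []
    while cur.peek() is not None and cur.peek().isdigit():
        digits.append(cur.take())
    if not digits:
        raise SpecParseError(f"expected a number, got {cur.peek()!r}")
    return int("".join(digits))


def _read_alpha(cur: _Cursor) -> float:
    whole = _read_int(cur)
    cur.expect(".")
    frac = []
    while cur.peek() is not None and cur.peek().isdigit():
        frac.append(cur.take())
    if len(frac) != ALPHA_DECIMALS:
        raise SpecParseError(
            f"loss_weight needs exactly {ALPHA_DECIMALS} decimals, got {len(frac)}"
        )
    val = whole + int("".join(frac)) / 10**ALPHA_DECIMALS
    if not 0.0 <= val <= 1.0:
        raise SpecParseError(f"loss_weight {val} outside [0, 1]")
    return val


def _check_range(kind: str, name: str, value: int) -> None:
    lo, hi = HYPERPARAM_RANGES[(kind, name)]
    if not lo <= value <= hi:
        raise SpecParseError(f"{kind} {name}={value} outside legal range [{lo}, {hi}]")


def parse_spec(text: str) -> NetworkSpec:
    """Parse canonical spec text into a :class:`NetworkSpec`.

    Raises :class:`ScaffoldError` when the fixed markers are missing,
    duplicated or misordered, :class:`SpecParseError` on any other grammar
    or hyperparameter-range violation.
    """
    toks = text.split()
    for marker in ("input", "merge", "output", "loss_weight"):
        n = toks.count(marker)
        if n != 1:
            raise ScaffoldError(f"scaffold marker {marker!r} appears {n} times")
    cur = _Cursor(toks)
    if cur.peek() != "input":
        raise ScaffoldError("spec must start with the input marker")
    cur.take()
    cur.expect(";")

    layers: list[LayerSpec] = []
    while cur.peek() not in ("merge", None):
        kind = cur.take()
        if kind == "conv":
            filters = _read_int(cur)
            cur.expect(",")
            kernel = _read_int(cur)
            act = cur.take()
            if act not in ACTIVATIONS:
                raise SpecParseError(f"bad activation {act!r}")
            _check_range("conv", "filters", filters)
            _check_range("conv", "kernel", kernel)
            layers.append(
                LayerSpec("conv", (("filters", filters), ("kernel", kernel)), act)
            )
        elif kind == "pool":
            size = _read_int(cur)
            _check_range("pool", "size", size)
            layers.append(LayerSpec("pool", (("size", size),)))
        elif kind == "dense":
            units = _read_int(cur)
            act = cur.take()
            if act not in ACTIVATIONS:
                raise SpecParseError(f"bad activation {act!r}")
            _check_range("dense", "units", units)
            layers.append(LayerSpec("dense", (("units", units),), act))
        elif kind == "dropout":
            pct = _read_int(cur)
            _check_range("dropout", "percent", pct)
            layers.append(LayerSpec("dropout", (("percent", pct),)))
        elif kind in ("output", "loss_weight"):
            raise ScaffoldError(f"{kind!r} before merge marker")
        else:
            raise SpecParseError(f"unknown layer kind {kind!r}")
        cur.expect(";")

    if cur.peek() is None:
        raise ScaffoldError("missing merge marker")
    cur.expect("merge")
    cur.expect(";")
    cur.expect("loss_weight")
    alpha = _read_alpha(cur)
    cur.expect(";")
    cur.expect("output")
    cur.expect(";")
    if cur.peek() is not None:
        raise SpecParseError(f"trailing tokens after output: {cur.peek()!r}")
    return NetworkSpec(tuple(layers), alpha)


@dataclass(frozen=True)
class BuildConfig:
    """Shapes and limits under which a spec is built.

    ``genotype_units`` and ``head_units`` size the fixed (scaffold) genotype
    branch and post-merge head; they are part of the dialect's scaffold, not
    heritable.
    """

    image_shape: tuple[int, int] = (28, 28)
    n_classes: int = 10
    genotype_length: int = 100
    genotype_units: int = 32
    head_units: int = 64
    parameter_cap: int = 2_000_000


@dataclass(frozen=True)
class BuildReport:
    """Outcome of attempting to build a network from a spec.

    ``valid`` iff ``error_kind == "none"``; ``parameter_count`` is defined
    whenever parsing succeeded (it may exceed the cap, in which case the
    report is invalid with kind ``parameter-cap-exceeded``).
    """

    valid: bool
    parameter_count: int | None
    error_kind: str  # parse-error | scaffold-violation | shape-mismatch | parameter-cap-exceeded | none
    detail: str = ""


def _layer_shapes(
    spec: NetworkSpec, config: BuildConfig
) -> tuple[list[tuple], int]:
    """Propagate shapes through the hidden chain; return (shapes, params).

    Image tensors are (rows, cols, channels); after a dense layer the branch
    is flat and is a single int.  Raises SpecError subclasses on mismatch.
    """
    m, n = config.image_shape
    shape: tuple | int = (m, n, 1)
    params = 0
    shapes = []
    for lay in spec.layers:
        if lay.kind == "conv":
            if not isinstance(shape, tuple):
                raise SpecParseError("conv after flatten")
            r, c, ch = shape
            f, ks = lay.get("filters"), lay.get("kernel")
            if ks > r or ks > c:
                raise SpecParseError(f"kernel {ks} larger than image {r}x{c}")
            params += f * (ks * ks * ch + 1)
            shape = (r, c, f)  # 'same' padding, stride 1
        elif lay.kind == "pool":
            if not isinstance(shape, tuple):
                raise SpecParseError("pool after flatten")
            r, c, ch = shape
            s = lay.get("size")
            r2, c2 = r // s, c // s
            if r2 < 1 or c2 < 1:
                raise SpecParseError(f"pool {s} collapses image {r}x{c}")
            shape = (r2, c2, ch)
        elif lay.kind == "dense":
            a = shape if isinstance(shape, int) else shape[0] * shape[1] * shape[2]
            u = lay.get("units")
            params += u * (a + 1)
            shape = u
        elif lay.kind == "dropout":
            pass
        shapes.append(shape)

    flat = shape if isinstance(shape, int) else shape[0] * shape[1] * shape[2]
    k, gu, hu, L = (
        config.genotype_length,
        config.genotype_units,
        config.head_units,
        config.n_classes,
    )
    params += gu * (k + 1)            # genotype branch (scaffold)
    merged = flat + gu
    params += hu * (merged + 1)       # shared head
    params += L * (hu + 1)            # classification output
    params += k * (hu + 1)            # replication output
    shapes.append(("merged", merged))
    return shapes, params


def build_network(spec: NetworkSpec | str, config: BuildConfig | None = None) -> BuildReport:
    """Validate a spec and report its closed-form trainable-parameter count.

    Pure and deterministic; never raises -- every failure mode is encoded in
    ``error_kind``.
    """
    config = config or BuildConfig()
    if isinstance(spec, str):
        try:
            spec = parse_spec(spec)
        except ScaffoldError as e:
            return BuildReport(False, None, "scaffold-violation", str(e))
        except SpecError as e:
            return BuildReport(False, None, "parse-error", str(e))
    try:
        _, params = _layer_shapes(spec, config)
    except SpecError as e:
        return BuildReport(False, None, "shape-mismatch", str(e))
    if params > config.parameter_cap:
        return BuildReport(
            False, params, "parameter-cap-exceeded",
            f"{params} > cap {config.parameter_cap}",
        )
    return BuildReport(True, params, "none")
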