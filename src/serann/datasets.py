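"""Classification datasets: synthetic glyphs and the IDX binary format.

The default image source is a built-in generator of noisy geometric glyphs
(digit-like strokes on an m x n grayscale grid), so the whole framework runs
and tests offline.  Real handwritten-digit data in IDX format can be loaded
instead via :func:`read_idx_images`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SyntheticImageConfig", "make_synthetic_images",
    "read_idx", "read_idx_images", "write_idx", "IdxFormatError",
]


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Configuration of the glyph generator.

    ``noise`` is the per-pixel Gaussian noise scale; ``jitter`` the maximum
    whole-glyph translation in pixels.  Train and eval sets are disjoint by
    construction (independent draws of the noise and jitter).
    """

    n_classes: int = 10
    image_shape: tuple[int, int] = (28, 28)
    train_size: int = 500
    eval_size: int = 200
    noise: float = 0.15
    jitter: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        m, n = self.image_shape
        if m < 6 or n < 6:
            raise ValueError("images must be at least 6x6")


def _glyph_template(cls: int, m: int, n: int) -> np.ndarray:
    """Deterministic stroke pattern for a class id; patterns are pairwise
    distinct for cls < 10 on any grid >= 6x6."""
    img = np.zeros((m, n))
    mid_r, mid_c = m // 2, n // 2
    q_r, q_c = m // 4, n // 4
    if cls % 10 == 0:      # box outline
        img[q_r, q_c:n - q_c] = 1
        img[m - q_r - 1, q_c:n - q_c] = 1
        img[q_r:m - q_r, q_c] = 1
        img[q_r:m - q_r, n - q_c - 1] = 1
    elif cls % 10 == 1:    # vertical bar
        img[q_r:m - q_r, mid_c - 1:mid_c + 1] = 1
    elif cls % 10 == 2:    # horizontal bar
        img[mid_r - 1:mid_r + 1, q_c:n - q_c] = 1
    elif cls % 10 == 3:    # main diagonal
        for i in range(min(m, n)):
            img[i, i] = 1
    elif cls % 10 == 4:    # cross
        img[mid_r, :] = 1
        img[:, mid_c] = 1
    elif cls % 10 == 5:    # anti-diagonal
        for i in range(min(m, n)):
            img[i, n - 1 - i] = 1
    elif cls % 10 == 6:    # top-half fill
        img[:mid_r, q_c:n - q_c] = 1
    elif cls % 10 == 7:    # bottom-half fill
        img[mid_r:, q_c:n - q_c] = 1
    elif cls % 10 == 8:    # left vertical + horizontal mid
        img[:, q_c] = 1
        img[mid_r, :] = 1
    else:                  # two horizontal bars
        img[q_r, :] = 1
        img[m - q_r - 1, :] = 1
    return img


def _render(template: np.ndarray, cfg: SyntheticImageConfig,
            rng: np.random.Generator) -> np.ndarray:
    m, n = template.shape
    img = template
    if cfg.jitter > 0:
        dr = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
        dc = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
        img = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
    img = img + rng.normal(0.0, cfg.noise, size=(m, n))
    return np.clip(img, 0.0, 1.0)


def make_synthetic_images(cfg: SyntheticImageConfig,
                          rng: np.random.Generator | None = None):
    """Generate (train_X, train_Y, eval_X, eval_Y) with balanced labels.

    Labels are one-hot; pixel values lie in [0, 1]; output is reproducible
    per seed.  Raises if two class templates collide.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    m, n = cfg.image_shape
    L = cfg.n_classes
    templates = [_glyph_template(c, m, n) for c in range(L)]
    for a in range(L):
        for b in range(a + 1, L):
            if np.array_equal(templates[a], templates[b]):
                raise ValueError(f"template collision between classes {a} and {b}")

    def build(size: int):
        X = np.empty((size, m, n))
        Y = np.zeros((size, L))
        for idx in range(size):
            cls = idx % L  # round-robin: exactly balanced when L | size
            X[idx] = _render(templates[cls], cfg, rng)
            Y[idx, cls] = 1.0
        perm = rng.permutation(size)
        return X[perm], Y[perm]

    train_X, train_Y = build(cfg.train_size)
    eval_X, eval_Y = build(cfg.eval_size)
    return train_X, train_Y, eval_X, eval_Y


class IdxFormatError(ValueError):
    """Malformed IDX header or truncated payload."""


_IDX_DTYPES = {
    0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
    0x0D: ">f4", 0x0E: ">f8",
}


def read_idx(path) -> np.ndarray:
    """Read one array in the IDX binary format (big-endian)."""
    with open(path, "rb") as fh:
        header = fh.read(4)
        if len(header) < 4 or header[0] != 0 or header[1] != 0:
            raise IdxFormatError("bad magic number")
        dtype_code, ndim = header[2], header[3]
        if dtype_code not in _IDX_DTYPES:
            raise IdxFormatError(f"unknown dtype code 0x{dtype_code:02x}")
        dims_raw = fh.read(4 * ndim)
        if len(dims_raw) < 4 * ndim:
            raise IdxFormatError("truncated dimension header")
        dims = struct.unpack(f">{ndim}I", dims_raw)
        dtype = np.dtype(_IDX_DTYPES[dtype_code])
        count = int(np.prod(dims)) if dims else 1
        payload = fh.read(count * dtype.itemsize)
        if len(payload) < count * dtype.itemsize:
            raise IdxFormatError("truncated payload")
        return np.frombuffer(payload, dtype=dtype).reshape(dims)


def write_idx(arr: np.ndarray, path) -> None:
    """Write a uint8 array in IDX format (for round-trip tests/fixtures)."""
    arr = np.ascontiguousarray(arr, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, 0x08, arr.ndim]))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.tobytes())


def read_idx_images(images_path, labels_path, n_classes: int | None = None):
    """Load an IDX image file plus its IDX label file.

    Returns (X, Y): images scaled to [0, 1] with shape (count, m, n), labels
    one-hot over the class count (inferred from the labels if not given).
    """
    X = read_idx(images_path)
    if X.ndim != 3:
        raise IdxFormatError(f"expected 3-D image array, got {X.ndim}-D")
    labels = read_idx(labels_path)
    if labels.ndim != 1 or labels.shape[0] != X.shape[0]:
        raise IdxFormatError("label count does not match image count")
    L = n_classes or int(labels.max()) + 1
    Y = np.zeros((labels.shape[0], L))
    Y[np.arange(labels.shape[0]), labels.astype(int)] = 1.0
    return X.astype(float) / 255.0, Y
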