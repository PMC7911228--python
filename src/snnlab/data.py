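"""Synthetic digit images and the MNIST IDX container format.

The procedural generator renders the ten digits from fixed handwriting-like
stroke templates (loops, arcs and diagonals with antialiased edges) onto a
28x28 canvas (background 0, stroke cores 255), then applies a seeded integer
translation jitter and salt noise.  It stands in
for handwritten-digit data wherever a small, fully reproducible labelled set
is needed; real MNIST files can be swapped in through the IDX reader.

IDX layout (big-endian): images files start with magic 0x00000803 followed
by three 32-bit dimensions (n, rows, cols) and n*rows*cols unsigned bytes;
labels files start with magic 0x00000801, one 32-bit count, and n bytes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledImageSet",
    "digit_template",
    "generate_digits",
    "write_idx",
    "read_idx",
    "write_idx_images",
    "write_idx_labels",
    "read_idx_images",
    "read_idx_labels",
    "IdxFormatError",
]

IMAGE_MAGIC = 0x00000803
LABEL_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """Malformed IDX payload; the message names the offending byte offset."""


@dataclass
class LabeledImageSet:
    """A stack of 28x28 uint8 images with integer labels 0-9."""

    images: np.ndarray
    labels: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    def split(self, n_first: int) -> tuple["LabeledImageSet", "LabeledImageSet"]:
        return (
            LabeledImageSet(self.images[:n_first], self.labels[:n_first], self.seed),
            LabeledImageSet(self.images[n_first:], self.labels[n_first:], self.seed),
        )


# Digit templates are drawn as handwriting-like stroke paths (loops, arcs
# and diagonals) on a 16x22 glyph box, then antialiased with a 3x3 box blur.
# Two properties matter for downstream latency coding: stroke edges are
# *graded* (so pixel values, and hence spike latencies, spread over the
# presentation window instead of collapsing onto one instant), and every
# class keeps a substantial uniquely-covered region (handwritten digit
# classes overlap only partially — unlike, say, seven-segment renderings,
# where every digit is a subset of the 8).


def _mark(canvas: np.ndarray, xs, ys) -> None:
    for x, y in zip(xs, ys):
        canvas[int(round(y)): int(round(y)) + 2,
               int(round(x)): int(round(x)) + 2] = 1.0


def _line(canvas, p0, p1, n=60) -> None:
    _mark(canvas, np.linspace(p0[0], p1[0], n), np.linspace(p0[1], p1[1], n))


def _arc(canvas, cx, cy, rx, ry, a0, a1, n=120) -> None:
    t = np.linspace(a0, a1, n)
    _mark(canvas, cx + rx * np.cos(t), cy + ry * np.sin(t))


def _render(digit: int) -> np.ndarray:
    c = np.zeros((22, 16))
    pi = np.pi
    if digit == 0:
        _arc(c, 7.5, 9.5, 5.0, 7.5, 0, 2 * pi)
    elif digit == 1:
        _line(c, (3, 5), (8, 1)); _line(c, (8, 1), (8, 17))
    elif digit == 2:
        _arc(c, 7, 5, 4.5, 4, pi, 2 * pi)
        _line(c, (11.5, 5), (2, 16)); _line(c, (2, 17), (13, 17))
    elif digit == 3:
        _arc(c, 7, 5, 4, 4, 0.8 * pi, 2 * pi)
        _arc(c, 8, 12.5, 4.5, 4.5, -pi / 2, 0.85 * pi)
    elif digit == 4:
        _line(c, (9, 1), (2, 12)); _line(c, (2, 12), (14, 12))
        _line(c, (10, 6), (10, 18))
    elif digit == 5:
        _line(c, (12, 1), (3, 1)); _line(c, (3, 1), (3, 8))
        _arc(c, 7.5, 12, 4.5, 5, -pi / 2, 0.8 * pi)
    elif digit == 6:
        _arc(c, 9, 3, 5, 3.2, 0.9 * pi, 1.6 * pi)
        _line(c, (3.5, 5), (2.5, 12))
        _arc(c, 7.5, 13, 4.8, 4.5, 0, 2 * pi)
    elif digit == 7:
        _line(c, (2, 1), (13, 1)); _line(c, (13, 1), (5, 18))
    elif digit == 8:
        _arc(c, 7.5, 5, 3.6, 3.8, 0, 2 * pi)
        _arc(c, 7.5, 13.5, 4.6, 4.6, 0, 2 * pi)
    elif digit == 9:
        _arc(c, 7, 5.5, 4.5, 4.3, 0, 2 * pi)
        _line(c, (11.3, 6.5), (8, 18))
    big = np.zeros((28, 28))
    big[4:26, 7:23] = c
    blur = np.zeros_like(big)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            blur += np.roll(big, (dy, dx), (0, 1))
    out = np.clip(big * 255 * 0.55 + blur / 9 * 255 * 0.65, 0, 255)
    return out.astype(np.uint8)


_TEMPLATE_CACHE: dict[int, np.ndarray] = {}


def digit_template(digit: int) -> np.ndarray:
    """Canonical 28x28 stroke template of one digit (0 = background, bright
    stroke cores at 255 with graded antialiased edges)."""
    if not 0 <= digit <= 9:
        raise ValueError("digit must be in 0..9")
    if digit not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[digit] = _render(digit)
    return _TEMPLATE_CACHE[digit].copy()


def generate_digits(n: int, seed: int = 0, jitter_px: int = 1,
                    noise_level: float = 0.02) -> LabeledImageSet:
    """Render ``n`` labelled digit images.

    Labels cycle 0..9 round-robin (class counts differ by at most one).
    Each image is the digit's template shifted by a uniform integer offset
    in [-jitter_px, jitter_px] on both axes, with each pixel independently
    set to 255 with probability ``noise_level`` (salt noise).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if jitter_px < 0 or not 0 <= noise_level <= 1:
        raise ValueError("jitter_px must be >= 0 and noise_level in [0, 1]")
    rng = np.random.default_rng(seed)
    templates = [digit_template(d) for d in range(10)]
    labels = np.arange(n) % 10
    images = np.empty((n, 28, 28), dtype=np.uint8)
    for i, lab in enumerate(labels):
        img = templates[lab]
        if jitter_px:
            dy, dx = rng.integers(-jitter_px, jitter_px + 1, size=2)
            img = np.roll(img, (dy, dx), axis=(0, 1))
        img = img.copy()
        if noise_level:
            img[rng.random((28, 28)) < noise_level] = 255
        images[i] = img
    return LabeledImageSet(images=images, labels=labels, seed=seed)


def write_idx_images(images: np.ndarray, path) -> None:
    images = np.asarray(images, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IMAGE_MAGIC, n, rows, cols))
        fh.write(images.tobytes())


def write_idx_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", LABEL_MAGIC, len(labels)))
        fh.write(labels.tobytes())


def _read_exact(fh, n_bytes: int, offset: int, what: str) -> bytes:
    buf = fh.read(n_bytes)
    if len(buf) != n_bytes:
        raise IdxFormatError(
            f"truncated {what}: expected {n_bytes} bytes at offset {offset}, "
            f"got {len(buf)}")
    return buf


def read_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = _read_exact(fh, 16, 0, "image header")
        magic, n, rows, cols = struct.unpack(">IIII", header)
        if magic != IMAGE_MAGIC:
            raise IdxFormatError(
                f"bad image magic 0x{magic:08x} at offset 0 "
                f"(expected 0x{IMAGE_MAGIC:08x})")
        payload = _read_exact(fh, n * rows * cols, 16, "image payload")
    return np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)


def read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = _read_exact(fh, 8, 0, "label header")
        magic, n = struct.unpack(">II", header)
        if magic != LABEL_MAGIC:
            raise IdxFormatError(
                f"bad label magic 0x{magic:08x} at offset 0 "
                f"(expected 0x{LABEL_MAGIC:08x})")
        payload = _read_exact(fh, n, 8, "label payload")
    return np.frombuffer(payload, dtype=np.uint8).astype(np.int64)


def _paths(path) -> tuple[Path, Path]:
    """A prefix ``foo`` maps to ``foo-images.idx`` / ``foo-labels.idx``."""
    prefix = Path(path)
    return (prefix.parent / f"{prefix.name}-images.idx",
            prefix.parent / f"{prefix.name}-labels.idx")


def write_idx(dataset: LabeledImageSet, path) -> tuple[Path, Path]:
    """Write images and labels next to each other under a common prefix."""
    img_path, lab_path = _paths(path)
    write_idx_images(dataset.images, img_path)
    write_idx_labels(dataset.labels, lab_path)
    return img_path, lab_path


def read_idx(path) -> LabeledImageSet:
    """Read a dataset written by :func:`write_idx` (or a pair of standard
    MNIST files renamed to the ``<prefix>-images.idx`` convention)."""
    img_path, lab_path = _paths(path)
    return LabeledImageSet(images=read_idx_images(img_path),
                           labels=read_idx_labels(lab_path))
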