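"""Binary test patterns with known fractal dimension.

These rasters are the validation substrate for the dimension estimators:
sets whose box-counting / sandbox dimensions are known analytically
(filled square, line, disk, Sierpinski gasket, Koch curve) plus a random
branching tree whose dimension is only known to lie strictly between 1
and 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line

__all__ = ["FractalFixture", "FIXTURE_KINDS", "generate_fixture"]

FIXTURE_KINDS = (
    "filled_square",
    "straight_line",
    "sierpinski_gasket",
    "koch_curve",
    "branching_tree",
    "uniform_disk",
)


@dataclass(frozen=True)
class FractalFixture:
    """A binary raster together with its analytic dimension, if one exists."""

    image: np.ndarray  # bool, object = True
    kind: str
    true_dimension: float | None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.image.sum() < 1:
            raise ValueError("fixture image must contain at least one object pixel")
        if self.true_dimension is not None and not 0.0 <= self.true_dimension <= 2.0:
            raise ValueError("true_dimension must lie in [0, 2]")


def _sierpinski(size: int, depth: int) -> np.ndarray:
    """Right-angle Sierpinski gasket, exactly self-similar at dyadic scales.

    A cell (i, j) of the depth-level 2^depth x 2^depth grid is occupied iff
    i & j == 0, which yields exactly 3^depth occupied base cells; each base
    cell is filled solid.  Dyadic box counts are then exact: a grid of boxes
    of side size / 2^k contains 3^k occupied boxes for k <= depth.
    """
    cells = 1 << depth
    if size % cells != 0:
        raise ValueError(
            f"size {size} must be divisible by 2**depth = {cells} for an exact gasket"
        )
    i, j = np.meshgrid(np.arange(cells), np.arange(cells), indexing="ij")
    base = (i & j) == 0
    return np.kron(base, np.ones((size // cells, size // cells), dtype=bool))


def _koch_points(depth: int) -> np.ndarray:
    """Vertex chain of the Koch curve on the unit segment, bulging upward."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot = np.array(
        [
            [math.cos(math.pi / 3), -math.sin(math.pi / 3)],
            [math.sin(math.pi / 3), math.cos(math.pi / 3)],
        ]
    )
    for _ in range(depth):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            v = (b - a) / 3.0
            p1 = a + v
            p2 = p1 + rot @ v
            p3 = a + 2 * v
            new.extend([p1, p2, p3, b])
        pts = np.asarray(new)
    return pts


def _koch(size: int, depth: int) -> np.ndarray:
    img = np.zeros((size, size), dtype=bool)
    pts = _koch_points(depth)
    margin = 2
    span = size - 1 - 2 * margin
    cols = margin + pts[:, 0] * span
    # curve height is sqrt(3)/6 of its width; anchor near the bottom edge
    rows = (size - 1 - margin) - pts[:, 1] * span
    cols = np.clip(np.round(cols).astype(int), 0, size - 1)
    rows = np.clip(np.round(rows).astype(int), 0, size - 1)
    for k in range(len(pts) - 1):
        rr, cc = _draw_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
        img[rr, cc] = True
    return img


def _branching_tree(size: int, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Random binary branching tree drawn with one-pixel strokes."""
    img = np.zeros((size, size), dtype=bool)

    def grow(r: float, c: float, angle: float, length: float, level: int) -> None:
        if level == 0 or length < 2.0:
            return
        r2 = r - length * math.cos(angle)
        c2 = c + length * math.sin(angle)
        rr, cc = _draw_line(
            int(round(r)), int(round(c)), int(round(r2)), int(round(c2))
        )
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[keep], cc[keep]] = True
        spread = math.radians(45.0)
        for s in (-1.0, 1.0):
            jitter = rng.normal(0.0, 0.12)
            grow(r2, c2, angle + s * spread + jitter, length * 0.82, level - 1)

    grow(size - 1, size / 2, 0.0, size * 0.22, depth)
    return img


def generate_fixture(
    kind: str, size: int = 256, depth: int = 5, seed: int = 0
) -> FractalFixture:
    """Generate a named binary pattern of known (or unknown) dimension.

    Parameters
    ----------
    kind:
        One of :data:`FIXTURE_KINDS`.
    size:
        Raster side length in pixels (>= 32).  ``sierpinski_gasket`` requires
        ``size`` divisible by ``2**depth``.
    depth:
        Recursion level for the self-similar kinds (>= 1).
    seed:
        RNG seed; only the ``branching_tree`` kind is stochastic.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if size < 32:
        raise ValueError("size must be >= 32")
    if kind in ("sierpinski_gasket", "koch_curve", "branching_tree") and depth < 1:
        raise ValueError("depth must be >= 1 for recursive kinds")

    dim: float | None
    if kind == "filled_square":
        img = np.ones((size, size), dtype=bool)
        dim = 2.0
    elif kind == "straight_line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
        dim = 1.0
    elif kind == "uniform_disk":
        img = np.zeros((size, size), dtype=bool)
        rr, cc = _draw_disk((size / 2.0 - 0.5, size / 2.0 - 0.5), size / 2.0 - 1.0)
        img[rr, cc] = True
        dim = 2.0
    elif kind == "sierpinski_gasket":
        img = _sierpinski(size, depth)
        dim = math.log(3) / math.log(2)
    elif kind == "koch_curve":
        img = _koch(size, depth)
        dim = math.log(4) / math.log(3)
    else:  # branching_tree
        img = _branching_tree(size, depth, np.random.default_rng(seed))
        dim = None
    return FractalFixture(image=img, kind=kind, true_dimension=dim, seed=seed)
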