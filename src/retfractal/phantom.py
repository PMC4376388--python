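"""Fundus-like vascular phantoms with ground-truth vessel masks.

A phantom is a stochastic binary branching tree rooted at a small disc (the
optic-disc analogue), rasterized with geometrically decaying vessel widths,
and rendered as a grayscale image in which vessels are darker than the
background — the contrast polarity of a fundus photograph.  An optional
one-pixel bright centerline emulates the central light reflex.  Phantoms
give every downstream stage (segmentation, cleanup, skeletonization,
fractal estimation, observer agreement) a ground truth to be scored
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk
from skimage.draw import line as _draw_line
_STRUCT8 = np.ones((3, 3), dtype=bool)

__all__ = ["PhantomParams", "VesselPhantom", "generate_phantom", "perturb_mask"]

#: default raster shape (rows, cols) matching the working resolution of the
#: vessel pipeline
DEFAULT_SHAPE = (685, 584)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and rendering parameters of a vascular phantom.

    depth:
        number of branching generations (>= 2).
    n_roots:
        primary vessels leaving the optic-disc analogue.
    branch_angle_spread:
        half-angle (degrees) between daughter branches at a bifurcation.
    width_decay:
        daughter width / parent width (geometric decay along the tree).
    length_decay:
        daughter length / parent length.
    initial_width / initial_length:
        trunk width and length in pixels.
    noise_level:
        sigma of additive Gaussian noise on the unit-range intensity image.
    central_reflex:
        render a 1-px bright centerline inside each vessel.
    """

    depth: int = 6
    n_roots: int = 6
    branch_angle_spread: float = 40.0
    width_decay: float = 0.80
    length_decay: float = 0.80
    initial_width: float = 6.0
    initial_length: float = 95.0
    angle_jitter: float = 0.14
    noise_level: float = 0.0
    central_reflex: bool = False
    shape: tuple[int, int] = DEFAULT_SHAPE
    disc_radius: float = 16.0
    background: float = 0.85
    vessel_intensity: float = 0.35


@dataclass(frozen=True)
class VesselPhantom:
    intensity_image: np.ndarray  # float in [0, 1]
    truth_mask: np.ndarray  # bool
    params: PhantomParams
    seed: int

    def __post_init__(self) -> None:
        if self.intensity_image.shape != self.truth_mask.shape:
            raise ValueError("intensity_image and truth_mask shapes must agree")


def _stamp_segment(mask, r0, c0, r1, c1, width) -> None:
    """Draw a thick segment by stamping discs along its centerline."""
    h, w = mask.shape
    rr, cc = _draw_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    radius = max(width / 2.0, 0.5)
    for r, c in zip(rr, cc):
        dr, dc = _draw_disk((r, c), radius, shape=(h, w))
        mask[dr, dc] = True


def generate_phantom(
    params: PhantomParams | None = None, seed: int = 0
) -> VesselPhantom:
    """Generate a fundus-like phantom; deterministic given ``seed``."""
    p = params or PhantomParams()
    if p.depth < 2:
        raise ValueError("branching depth must be >= 2")
    if p.noise_level < 0:
        raise ValueError("noise level must be >= 0")
    if p.initial_length <= 0 or p.length_decay <= 0:
        raise ValueError("degenerate geometry: branch lengths must be positive")

    rng = np.random.default_rng(seed)
    h, w = p.shape
    mask = np.zeros((h, w), dtype=bool)
    centerline = np.zeros((h, w), dtype=bool)

    # optic-disc analogue near the nasal edge, vessels fan out from it
    disc_r, disc_c = h / 2.0, w * 0.16
    dr, dc = _draw_disk((disc_r, disc_c), p.disc_radius, shape=(h, w))
    mask[dr, dc] = True

    segments: list[tuple[float, float, float, float, float, int]] = []
    base_angles = np.linspace(-75.0, 75.0, p.n_roots)  # degrees, 0 = +col axis
    for a in base_angles:
        ang = math.radians(a + rng.normal(0.0, 4.0))
        segments.append((disc_r, disc_c, ang, p.initial_length, p.initial_width, p.depth))

    while segments:
        r0, c0, ang, length, width, level = segments.pop()
        # mild curvature: split the branch into two sub-segments
        steps = 2
        r, c, a = r0, c0, ang
        for _ in range(steps):
            a += rng.normal(0.0, p.angle_jitter / 2.0)
            r1 = r + (length / steps) * math.sin(a)
            c1 = c + (length / steps) * math.cos(a)
            _stamp_segment(mask, r, c, r1, c1, width)
            rr, cc = _draw_line(int(round(r)), int(round(c)), int(round(r1)), int(round(c1)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            centerline[rr[keep], cc[keep]] = True
            r, c = r1, c1
        if level <= 1 or length * p.length_decay < 3.0:
            continue
        spread = math.radians(p.branch_angle_spread)
        for s in (-1.0, 1.0):
            segments.append(
                (
                    r,
                    c,
                    a + s * spread + rng.normal(0.0, p.angle_jitter),
                    length * p.length_decay,
                    width * p.width_decay,
                    level - 1,
                )
            )

    # keep only the component attached to the disc (off-image branches can
    # re-enter detached in principle)
    lbl, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    root_label = lbl[int(disc_r), int(disc_c)]
    mask = lbl == root_label

    img = np.full((h, w), p.background, dtype=float)
    img[mask] = p.vessel_intensity
    if p.central_reflex:
        reflex = centerline & ndi.binary_erosion(mask, _STRUCT8)
        img[reflex] = min(p.background - 0.1, 0.75)
    img = ndi.gaussian_filter(img, sigma=0.8)
    if p.noise_level > 0:
        img = img + rng.normal(0.0, p.noise_level, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return VesselPhantom(intensity_image=img, truth_mask=mask, params=p, seed=seed)


def perturb_mask(mask: np.ndarray, flip_rate: float, seed: int = 0) -> np.ndarray:
    """Simulate a second observer by toggling object-boundary pixels.

    Pixels on the inner boundary (object pixels with a background neighbour)
    and outer boundary (background pixels with an object neighbour) flip
    independently with probability ``flip_rate``; the interior bulk is
    untouched.  Deterministic given ``seed``.
    """
    if not 0.0 <= flip_rate <= 0.2:
        raise ValueError("flip_rate must lie in [0, 0.2]")
    mask = np.asarray(mask, dtype=bool)
    if flip_rate == 0.0:
        return mask.copy()
    inner = mask & ~ndi.binary_erosion(mask, _STRUCT8)
    outer = ndi.binary_dilation(mask, _STRUCT8) & ~mask
    boundary = inner | outer
    rng = np.random.default_rng(seed)
    flips = boundary & (rng.random(mask.shape) < flip_rate)
    return mask ^ flips
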