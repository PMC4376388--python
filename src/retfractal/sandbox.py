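"""Generalized sandbox estimation of the multifractal dimensions D0, D1, D2.

Masses M(R) — object-pixel counts inside discs of radius R centered on
random object points — grow as R^Dq in the scaling regime.  For q != 1,

    Dq = slope of (1 / (q - 1)) * log< (M(R)/M0)^(q-1) >  vs  log(R/L),

where <.> averages over seed points, M0 is the total object mass and L the
linear extent of the raster; the entropy dimension D1 uses the logarithmic
limit, the slope of < log(M(R)/M0) > vs log(R/L).  D0, D1 and D2 are the
capacity, entropy and correlation dimensions; for a multifractal measure
D0 >= D1 >= D2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .boxcount import estimate_dbox
from .vessel import skeletonize

__all__ = [
    "SandboxResult",
    "DimensionProfile",
    "sample_seed_points",
    "sandbox_masses",
    "generalized_dimension",
    "estimate_sandbox",
    "dimension_profile",
    "default_radii",
]


@dataclass(frozen=True)
class SandboxResult:
    points: np.ndarray  # (n, 2) row/col seed coordinates
    radii: np.ndarray
    masses: np.ndarray  # (n_points, n_radii)
    m0: int
    extent: float
    dq: dict[float, float]
    r_squared: dict[float, float]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DimensionProfile:
    """The four fractal dimensions of one image, plus fit diagnostics."""

    d_box: float
    d0: float
    d1: float
    d2: float
    box_r2: float
    sandbox_r2: dict[float, float]
    spectrum: dict[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"d_box": self.d_box, "d0": self.d0, "d1": self.d1, "d2": self.d2}


def default_radii(shape: tuple[int, int], n_steps: int = 12) -> np.ndarray:
    """Geometric radius schedule from 4 px to min(H, W) / 4."""
    rmax = min(shape) / 4.0
    if rmax <= 4.0:
        raise ValueError(f"image {shape} too small for the default radius schedule")
    return np.geomspace(4.0, rmax, n_steps)


def sample_seed_points(
    mask: np.ndarray, n_points: int = 1000, seed: int = 0
) -> np.ndarray:
    """Draw ``n_points`` uniformly among object pixels (deterministic given seed).

    If the mask holds fewer than ``n_points`` object pixels the draw is with
    replacement and a warning is issued.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValueError("empty mask: cannot sample seed points")
    rng = np.random.default_rng(seed)
    if len(coords) < n_points:
        warnings.warn(
            f"mask has {len(coords)} object pixels < {n_points} requested; "
            "sampling with replacement",
            stacklevel=2,
        )
        idx = rng.choice(len(coords), size=n_points, replace=True)
    else:
        idx = rng.choice(len(coords), size=n_points, replace=False)
    return coords[idx]


def sandbox_masses(
    mask: np.ndarray, points: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """M_i(R): object pixels within Euclidean distance R of each seed point.

    Discs are inclusive (a pixel at distance exactly R counts).  Returns an
    (n_points, n_radii) integer array, non-decreasing along the radius axis.
    """
    mask = np.asarray(mask, dtype=bool)
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if radii[-1] > min(mask.shape) / 2.0:
        raise ValueError("max radius exceeds half the image extent")
    coords = np.argwhere(mask).astype(float)
    tree = cKDTree(coords)
    pts = np.asarray(points, dtype=float)
    out = np.empty((len(pts), len(radii)), dtype=np.int64)
    # tiny epsilon makes the disc boundary inclusive despite float rounding
    for j, r in enumerate(radii):
        out[:, j] = tree.query_ball_point(pts, r + 1e-9, return_length=True)
    return out


def _border_valid(points: np.ndarray, radii: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """valid[i, j] — the R_j disc around point i lies fully inside the frame."""
    pts = np.asarray(points, dtype=float)
    h, w = shape
    dist_border = np.minimum.reduce(
        [pts[:, 0], h - 1 - pts[:, 0], pts[:, 1], w - 1 - pts[:, 1]]
    )
    return dist_border[:, None] >= radii[None, :]


def generalized_dimension(
    masses: np.ndarray,
    radii: np.ndarray,
    q: float,
    m0: int,
    extent: float,
    valid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Slope estimate of Dq from per-point mass curves; returns (Dq, R^2).

    ``valid`` masks (point, radius) pairs whose disc is truncated by the
    image border; such pairs are excluded from the per-radius average.
    Radii with no valid point, or zero masses inside a log, are dropped.
    """
    masses = np.asarray(masses, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if valid is None:
        valid = np.ones(masses.shape, dtype=bool)
    ok = valid & (masses > 0)
    rel = np.where(ok, masses / float(m0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if q == 1.0:
            y_per_r = np.nanmean(np.log(rel), axis=0)
        else:
            y_per_r = np.log(np.nanmean(rel ** (q - 1.0), axis=0)) / (q - 1.0)
    n_valid = ok.sum(axis=0)
    keep = (n_valid > 0) & np.isfinite(y_per_r)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable radii in the sandbox fit")
    x = np.log(radii[keep] / extent)
    y = y_per_r[keep]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def estimate_sandbox(
    mask: np.ndarray,
    n_points: int = 1000,
    radii: np.ndarray | None = None,
    qs: tuple[float, ...] = (0.0, 1.0, 2.0),
    seed: int = 0,
    exclude_border_points: bool = False,
) -> SandboxResult:
    """Sandbox dimensions Dq of a binary mask at the default settings.

    Normalizers: M0 = total object pixels, L = min(H, W).  Seed points
    whose largest discs leave the frame keep their smaller radii in the fit
    (default) or are excluded entirely (``exclude_border_points``).
    """
    mask = np.asarray(mask, dtype=bool)
    if radii is None:
        radii = default_radii(mask.shape)
    radii = np.asarray(radii, dtype=float)
    points = sample_seed_points(mask, n_points=n_points, seed=seed)
    valid = _border_valid(points, radii, mask.shape)
    if exclude_border_points:
        keep_pts = valid.all(axis=1)
        points = points[keep_pts]
        valid = valid[keep_pts]
    masses = sandbox_masses(mask, points, radii)
    m0 = int(mask.sum())
    extent = float(min(mask.shape))
    dq, r2 = {}, {}
    for q in qs:
        dq[q], r2[q] = generalized_dimension(masses, radii, q, m0, extent, valid)
    return SandboxResult(
        points=points,
        radii=radii,
        masses=masses,
        m0=m0,
        extent=extent,
        dq=dq,
        r_squared=r2,
        metadata={
            "n_points": n_points,
            "seed": seed,
            "normalizers": {"M0": m0, "L": extent},
            "border_policy": "exclude_points" if exclude_border_points else "truncate_radii",
        },
    )


def dimension_profile(
    mask: np.ndarray,
    substrate: str = "skeleton",
    n_points: int = 1000,
    seed: int = 0,
    q_grid: tuple[float, ...] | None = None,
) -> DimensionProfile:
    """All four dimensions (D_box, D0, D1, D2) of one vessel mask.

    ``substrate`` selects whether estimation runs on the thinned skeleton
    (default — fractal measures are more sensitive on skeletons) or on the
    width-bearing map.  ``q_grid`` optionally adds a Dq spectrum over extra
    q values for multifractality inspection.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no dimensions to estimate")
    if substrate not in ("skeleton", "map"):
        raise ValueError("substrate must be 'skeleton' or 'map'")
    sub = skeletonize(mask) if substrate == "skeleton" else mask
    box = estimate_dbox(sub)
    qs: tuple[float, ...] = (0.0, 1.0, 2.0)
    if q_grid is not None:
        qs = tuple(sorted(set(qs) | set(float(q) for q in q_grid)))
    sb = estimate_sandbox(sub, n_points=n_points, seed=seed, qs=qs)
    spectrum = dict(sb.dq) if q_grid is not None else None
    return DimensionProfile(
        d_box=box.d_box,
        d0=sb.dq[0.0],
        d1=sb.dq[1.0],
        d2=sb.dq[2.0],
        box_r2=box.r_squared,
        sandbox_r2=sb.r_squared,
        spectrum=spectrum,
        metadata={"substrate": substrate, "seed": seed, "n_points": n_points},
    )
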