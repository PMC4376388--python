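"""Reading and writing masks, images and cohort tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["read_image", "read_mask", "write_mask", "write_image", "write_cohort", "read_cohort"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG intensity image as float in [0, 1]."""
    img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is object)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).astype(np.uint8))


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
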