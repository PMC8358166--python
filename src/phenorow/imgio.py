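"""Reading and writing images and binary masks.

All in-memory images are H×W×3 float arrays with intensities in [0, 1]
(row 0 at the top of the image); binary masks are H×W arrays in {0, 1}.
Raw 8-bit files are normalized by dividing by 255 on read.  Optional
rescaling (e.g. to 1000×750 for high-resolution field photos) uses
bilinear interpolation.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image


def load_image(path: str | os.PathLike, rescale: tuple[int, int] | None = None) -> np.ndarray:
    """Load an RGB image as a H×W×3 float array in [0, 1].

    Parameters
    ----------
    path
        PNG or JPEG file.
    rescale
        Optional ``(width, height)`` target; bilinear resampling.
    """
    with Image.open(path) as im:
        im = im.convert("RGB")
        if rescale is not None:
            im = im.resize(rescale, Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return arr


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a [0, 1] float RGB array as an 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a single-channel 0/255 PNG as a {0, 1} integer mask."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as a single-channel 0/255 PNG."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(m, mode="L").save(path)


def as_float_image(image: np.ndarray) -> np.ndarray:
    """Validate and return an H×W×3 float image with values in [0, 1]."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB array, got shape {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]; divide 8-bit data by 255")
    return arr
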