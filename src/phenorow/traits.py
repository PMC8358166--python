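"""Height measurement from an isolated, segmented plant mask.

The measurement restricts the mask to the plant's "center part" —
columns around the column-mean peak, trimmed where the column mean
drops below 10% of its maximum — so that stray pixels of neighboring
plants or leaves crossing the cut lines do not inflate the row extent.
Height is the row-index difference between the first row from below
and the first row from above whose (center-part) row mean exceeds
2.5% of the maximal row mean.  Heights are reported in pixels; no
pixel-to-physical calibration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isolation import RowCutResult, column_profile, row_profile


@dataclass(frozen=True)
class HeightMeasurement:
    """Plant height in pixels, with the rows/columns that defined it."""

    plant_id: str
    height_px: int
    top_row: int
    bottom_row: int
    left_cut: int
    right_cut: int
    peak_col: int


def center_crop(
    plant_mask: np.ndarray, rel_threshold: float = 0.10
) -> tuple[int, int, int]:
    """Center-part column interval of a plant mask.

    Finds the column-mean peak (ties → smallest index) and walks
    outward in both directions; each cut is the last column before the
    first column whose mean falls below ``rel_threshold`` × the peak
    mean.  If the mean never drops below the threshold the cut is the
    image edge.

    Returns ``(left_cut, right_cut, peak_col)``.
    """
    means = column_profile(plant_mask)
    cmax = means.max()
    if cmax <= 0:
        raise ValueError("all-zero plant mask")
    thr = rel_threshold * cmax
    peak = int(np.argmax(means))
    left = peak
    while left > 0 and means[left - 1] >= thr:
        left -= 1
    right = peak
    n = means.size
    while right < n - 1 and means[right + 1] >= thr:
        right += 1
    return left, right, peak


def measure_height(
    plant_mask: np.ndarray,
    plant_id: str = "plant",
    center_threshold: float = 0.10,
    row_threshold: float = 0.025,
) -> HeightMeasurement:
    """Measure a plant's height in pixels from its binary mask.

    The mask is first restricted to its center part (see
    :func:`center_crop`); the top and bottom rows are the first rows —
    scanning from above and from below — whose center-part row mean is
    strictly greater than ``row_threshold`` × the maximal row mean.
    Height is the index difference ``bottom_row − top_row`` (a single
    occupied row yields height 0).
    """
    left, right, peak = center_crop(plant_mask, rel_threshold=center_threshold)
    center = np.asarray(plant_mask)[:, left : right + 1]
    means = row_profile(center)
    rmax = means.max()
    if rmax <= 0:
        raise ValueError("degenerate center part: no plant pixels")
    occupied = np.flatnonzero(means > row_threshold * rmax)
    top = int(occupied[0])
    bottom = int(occupied[-1])
    return HeightMeasurement(
        plant_id=plant_id,
        height_px=bottom - top,
        top_row=top,
        bottom_row=bottom,
        left_cut=left,
        right_cut=right,
        peak_col=peak,
    )


def measure_band_height(cut: RowCutResult) -> int:
    """Vertical extent of the front-row band (its jump over time flags
    the onset of overlap between the front and background plant rows)."""
    return cut.lower_row - cut.upper_row
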