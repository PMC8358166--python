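"""Refining height measurements across a camera's time series of images.

A fixed camera photographs the same row of plants over the season, so
plant locations are nearly constant across frames while the camera may
jitter horizontally and individual frames may be unusable (occlusion,
wind, camera faults).  Four steps clean the series:

1. Row-cut every frame and track the front-row band height; a single
   upward mean-shift in band height marks the time at which the front
   row starts to overlap the rows behind it — frames from then on are
   discarded, since the front row is no longer separable.
2. Column-cut the remaining frames, count plants per frame, and keep
   only frames whose count equals the modal count m.
3. Stabilize the per-frame plant peak columns against camera jitter:
   each plant's peaks are replaced by its across-frame average plus a
   per-frame median shift, and the plant cuts are rebuilt from the
   stabilized peaks.
4. Re-measure each plant's height in every kept frame.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .isolation import RowCutResult, band_mask, column_cut, cuts_from_peaks, row_cut
from .traits import measure_band_height, measure_height

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# changepoint


def detect_changepoint(values: np.ndarray, penalty: float | None = None) -> int:
    """Most prominent single mean-shift in a series (at-most-one-change).

    Scans every split point, choosing the one minimizing the total
    within-segment sum of squares, and accepts it only if the
    log-likelihood improvement for a Normal mean-change model exceeds an
    SIC-style penalty (default ``2·log(n)``, two extra parameters: the
    second mean and the change location).  Returns the first index of
    the post-change regime, or ``len(values)`` when no change is found.
    """
    y = np.asarray(values, dtype=np.float64)
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    if penalty is None:
        penalty = 2.0 * np.log(n)
    css = np.concatenate([[0.0], np.cumsum(y)])
    css2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def sse(a: int, b: int) -> float:  # [a, b) with b > a
        s = css[b] - css[a]
        s2 = css2[b] - css2[a]
        return max(s2 - s * s / (b - a), 0.0)

    sse_null = sse(0, n)
    splits = np.arange(1, n)
    total = np.array([sse(0, int(k)) + sse(int(k), n) for k in splits])
    best = int(np.argmin(total))
    sse_best = total[best]
    scale = max(float(np.mean(y**2)), 1.0)
    if sse_null <= 1e-9 * n * scale:  # constant series up to rounding
        return n
    eps = 1e-12 * n * scale
    stat = n * (np.log(sse_null + eps) - np.log(sse_best + eps))
    if stat <= penalty:
        return n
    return int(splits[best])


def plant_count_mode(counts, expected: int | None = None) -> int:
    """Modal plant count across frames.

    Ties are broken toward ``expected`` (the number of seeds planted
    per row, when known), otherwise toward the larger count.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no counts")
    freq = Counter(counts)
    top = max(freq.values())
    tied = sorted(c for c, f in freq.items() if f == top)
    if expected is not None and expected in tied:
        return expected
    return tied[-1]


def select_valid_frames(counts, m: int, changepoint: int) -> list[int]:
    """Frame indices before the changepoint whose plant count equals m."""
    selected = [i for i, c in enumerate(counts) if i < changepoint and c == m]
    if not selected:
        logger.warning("no valid frames: no pre-changepoint frame has %d plants", m)
    return selected


# ---------------------------------------------------------------------------
# peak stabilization


def _lower_median(x: np.ndarray) -> np.ndarray:
    """Lower median along the last axis (deterministic for even sizes)."""
    s = np.sort(x, axis=-1)
    return s[..., (x.shape[-1] - 1) // 2]


def stabilize_peaks(peak_matrix: np.ndarray) -> np.ndarray:
    """Stabilize plant peak columns against horizontal camera jitter.

    ``peak_matrix`` is n frames × m plants of column peak indices
    I_p^(i,j).  Each plant's across-frame average Ī_p^(j) anchors its
    position; the per-frame shift is recovered as the (lower) median
    over plants of I_p^(i,j) minus the median of the averages:

        Î_p^(i,j) = Ī_p^(j) + med_j I_p^(i,j) − med_j Ī_p^(j)

    so a frame in which the whole row moved c columns gets all its
    peaks moved back by c.  Adjacent stabilized peak spacings are, by
    construction, identical across frames.
    """
    p = np.asarray(peak_matrix, dtype=np.float64)
    if p.ndim != 2 or p.size == 0:
        raise ValueError("peak matrix must be nonempty n×m")
    col_mean = p.mean(axis=0)  # Ī_p^(j)
    shift = _lower_median(p) - _lower_median(col_mean[None, :])[0]
    return col_mean[None, :] + shift[:, None]


# ---------------------------------------------------------------------------
# full series measurement


@dataclass
class SeriesResult:
    """Refined per-plant height series for one camera."""

    changepoint_index: int
    band_heights: list[int]
    plant_counts: list[int]
    modal_count: int
    valid_frames: list[int]
    stabilized_peaks: np.ndarray  # n_valid × m
    cuts_per_frame: dict[int, tuple[int, ...]]
    heights: dict[int, list[tuple[int, int]]]  # plant j -> [(frame, height_px)]
    skipped: dict[int, str] = field(default_factory=dict)


def measure_series(
    masks,
    expected_count: int | None = None,
    row_params: dict | None = None,
    col_params: dict | None = None,
    changepoint_penalty: float | None = None,
) -> SeriesResult:
    """Measure per-plant heights over a time-ordered series of masks.

    Steps: row-cut + band-height changepoint; per-frame plant counts +
    modal-count frame selection; peak stabilization + refined cuts;
    per-plant height measurement.  Frames on which a stage fails are
    skipped with a logged reason.
    """
    masks = list(masks)
    if len(masks) < 10:
        raise ValueError("need a series of at least 10 frames")
    row_params = row_params or {}
    col_params = col_params or {}

    row_cuts: list[RowCutResult | None] = []
    skipped: dict[int, str] = {}
    for i, m in enumerate(masks):
        try:
            row_cuts.append(row_cut(m, **row_params))
        except ValueError as exc:
            logger.warning("frame %d: row cut failed (%s)", i, exc)
            skipped[i] = f"row_cut: {exc}"
            row_cuts.append(None)

    band_heights = [measure_band_height(rc) if rc is not None else 0 for rc in row_cuts]
    cp = detect_changepoint(np.asarray(band_heights, dtype=float), penalty=changepoint_penalty)

    counts: list[int] = []
    col_cuts = []
    for i, (m, rc) in enumerate(zip(masks, row_cuts)):
        if rc is None:
            counts.append(0)
            col_cuts.append(None)
            continue
        try:
            cc = column_cut(band_mask(m, rc), **col_params)
            counts.append(cc.n_plants)
            col_cuts.append(cc)
        except ValueError as exc:
            logger.warning("frame %d: column cut failed (%s)", i, exc)
            skipped[i] = f"column_cut: {exc}"
            counts.append(0)
            col_cuts.append(None)

    usable = [c for i, c in enumerate(counts) if i < cp and c > 0]
    if not usable:
        raise ValueError("no usable frames before the changepoint")
    m_mode = plant_count_mode(usable, expected=expected_count)
    valid = select_valid_frames(counts, m_mode, cp)

    if valid:
        peak_matrix = np.array([col_cuts[i].peak_cols for i in valid], dtype=np.float64)
        stabilized = stabilize_peaks(peak_matrix)
    else:
        stabilized = np.empty((0, m_mode))

    cuts_per_frame: dict[int, tuple[int, ...]] = {}
    heights: dict[int, list[tuple[int, int]]] = {j: [] for j in range(m_mode)}
    for row_i, i in enumerate(valid):
        rc = row_cuts[i]
        band = band_mask(masks[i], rc)
        cuts, _ = cuts_from_peaks(stabilized[row_i], band.shape[1])
        cuts_per_frame[i] = cuts
        for j in range(m_mode):
            lo, hi = cuts[j], cuts[j + 1]
            sub = band[:, lo : hi + 1]
            try:
                hm = measure_height(sub, plant_id=f"plant{j}")
            except ValueError as exc:
                logger.warning("frame %d plant %d: height failed (%s)", i, j, exc)
                continue
            heights[j].append((i, hm.height_px))

    return SeriesResult(
        changepoint_index=cp,
        band_heights=band_heights,
        plant_counts=counts,
        modal_count=m_mode,
        valid_frames=valid,
        stabilized_peaks=stabilized,
        cuts_per_frame=cuts_per_frame,
        heights=heights,
        skipped=skipped,
    )
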