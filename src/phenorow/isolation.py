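"""Isolating the front row of plants and the individual plants within it.

Works on a segmented binary mask.  The row-cut finds the band of pixel
rows occupied by the front (bottom) row of plants: the per-row plant
fraction is smoothed with a loess smoother, peaks are called by
thresholding at a fraction R_v of the global maximum (runs closer than
S_r rows are merged), the bottom-most peak is taken as the front row,
and its band boundaries are the first rows whose smoothed fraction
drops below R_u (above) and R_l (below) times the peak value.

The column-cut then splits the band into individual plants: the per-
column plant fraction inside the band is squared (which sharpens the
peaks), peaks are called at a fraction C_h of the maximum with
segments closer than S_c columns merged, and cut points are placed at
midpoints between adjacent peak columns, with outer margins at D_I —
half the largest adjacent-peak spacing — beyond the first and last
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# profiles


def row_profile(mask: np.ndarray) -> np.ndarray:
    """Per-row mean of a binary mask (fraction of plant pixels per row)."""
    m = _as_mask(mask)
    return m.mean(axis=1)


def column_profile(mask: np.ndarray) -> np.ndarray:
    """Per-column mean of a binary mask."""
    m = _as_mask(mask)
    return m.mean(axis=0)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2 or m.size == 0:
        raise ValueError(f"expected a nonempty 2-D mask, got shape {m.shape}")
    return (m > 0).astype(np.float64)


# ---------------------------------------------------------------------------
# loess smoothing (local quadratic regression, tricube weights)


def smooth_profile(profile: np.ndarray, span: float = 0.05) -> np.ndarray:
    """Loess-smooth a 1-D profile.

    At each index a quadratic is fitted by weighted least squares to the
    ``span`` fraction of nearest points, with tricube weights on the
    scaled distances; the fit is evaluated at that index.  Exact on
    constant, linear and quadratic inputs.

    Parameters
    ----------
    profile
        1-D array, length ≥ 10.
    span
        Fraction of points in each local window, in (0, 1].
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("profile must be 1-D with at least 10 points")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = y.size
    q = max(int(np.ceil(span * n)), 4)  # at least 4 points for a stable quadratic
    q = min(q, n)
    x = np.arange(n, dtype=np.float64)
    out = np.empty(n)
    half = q // 2
    for i in range(n):
        lo = max(0, min(i - half, n - q))
        window = slice(lo, lo + q)
        xw = x[window] - i
        yw = y[window]
        dmax = np.abs(xw).max()
        if dmax == 0:
            out[i] = yw[0]
            continue
        u = np.abs(xw) / dmax
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        # boundary of the window gets weight 0; keep the fit well posed
        if np.count_nonzero(w) < 3:
            w = w + 1e-12
        basis = np.stack([np.ones_like(xw), xw, xw**2], axis=1)
        wsqrt = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(basis * wsqrt[:, None], yw * wsqrt, rcond=None)
        out[i] = coef[0]
    return out


# ---------------------------------------------------------------------------
# peak segment calling


@dataclass(frozen=True)
class PeakParams:
    """Thresholded local-maximum calling parameters.

    rel_threshold — threshold as a fraction of the profile's global max;
    min_gap — two above-threshold runs are separate segments iff the
    number of below-threshold indices between them is ≥ min_gap.
    """

    rel_threshold: float
    min_gap: int

    def __post_init__(self):
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError(f"rel_threshold must be in (0,1), got {self.rel_threshold}")
        if self.min_gap < 1:
            raise ValueError(f"min_gap must be ≥ 1, got {self.min_gap}")


@dataclass(frozen=True)
class PeakSegments:
    """Disjoint [start, end] index intervals (inclusive) with their peaks."""

    segments: tuple[tuple[int, int], ...]
    peak_indices: tuple[int, ...]
    peak_values: tuple[float, ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.segments)


def call_peak_segments(profile: np.ndarray, params: PeakParams) -> PeakSegments:
    """Group above-threshold indices into peak segments.

    The threshold is ``rel_threshold`` × the global maximum.  Maximal
    runs of strictly-above-threshold indices are found; adjacent runs
    separated by fewer than ``min_gap`` below-threshold indices are
    merged into one segment (which then spans the gap).  Each segment's
    peak is the argmax of the profile inside it (ties → smallest index).
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("profile must be a nonempty 1-D array")
    gmax = y.max()
    if gmax <= 0:
        raise ValueError("no peaks: profile has no positive values")
    thr = params.rel_threshold * gmax
    above = y > thr
    if not above.any():  # global max is above its own fraction, so unreachable
        raise ValueError("no peaks: no value above threshold")
    runs = _runs(above)
    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        gap = start - merged[-1][1] - 1
        if gap < params.min_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    segs, peaks, vals = [], [], []
    for start, end in merged:
        seg = y[start : end + 1]
        p = start + int(np.argmax(seg))
        segs.append((start, end))
        peaks.append(p)
        vals.append(float(y[p]))
    return PeakSegments(tuple(segs), tuple(peaks), tuple(vals), float(thr))


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) pairs."""
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# row cut


@dataclass(frozen=True)
class RowCutResult:
    """Front-row band: rows [upper_row, lower_row], row 0 at image top."""

    upper_row: int
    lower_row: int
    peak_row: int
    peak_value: float
    params: dict = field(default_factory=dict)

    @property
    def band_height(self) -> int:
        return self.lower_row - self.upper_row


def row_cut(
    mask: np.ndarray,
    span: float = 0.05,
    rel_threshold: float = 0.10,
    min_gap: int = 10,
    upper_frac: float = 0.075,
    lower_frac: float = 0.025,
) -> RowCutResult:
    """Locate the front (bottom) row of plants in a segmented mask.

    Smooths the row-mean profile, calls peak segments at
    ``rel_threshold`` of the global max (runs < ``min_gap`` rows apart
    merged), selects the bottom-most segment, and walks from its peak:
    upward to the first row whose smoothed value falls below
    ``upper_frac`` × peak value, downward to the first row below
    ``lower_frac`` × peak value.  Boundaries clip to the image edge.
    """
    profile = row_profile(mask)
    if profile.max() <= 0:
        raise ValueError("no front row: mask has no plant pixels")
    smoothed = smooth_profile(profile, span=span)
    smoothed = np.clip(smoothed, 0.0, None)
    segs = call_peak_segments(smoothed, PeakParams(rel_threshold, min_gap))
    # bottom-most segment (largest row index) is the front row
    peak_row = segs.peak_indices[-1]
    peak_value = segs.peak_values[-1]
    upper = peak_row
    while upper > 0 and smoothed[upper - 1] >= upper_frac * peak_value:
        upper -= 1
    if upper > 0:
        upper -= 1  # the first row *below* the threshold bounds the band
    n = profile.size
    lower = peak_row
    while lower < n - 1 and smoothed[lower + 1] >= lower_frac * peak_value:
        lower += 1
    if lower < n - 1:
        lower += 1
    return RowCutResult(
        upper_row=int(upper),
        lower_row=int(lower),
        peak_row=int(peak_row),
        peak_value=float(peak_value),
        params={
            "span": span,
            "rel_threshold": rel_threshold,
            "min_gap": min_gap,
            "upper_frac": upper_frac,
            "lower_frac": lower_frac,
        },
    )


def band_mask(mask: np.ndarray, cut: RowCutResult) -> np.ndarray:
    """The sub-mask of rows [upper_row, lower_row]."""
    return np.asarray(mask)[cut.upper_row : cut.lower_row + 1, :]


# ---------------------------------------------------------------------------
# column cut


@dataclass(frozen=True)
class ColumnCutResult:
    """Individual-plant separation of a front-row band.

    ``peak_cols`` are the m plant peak columns; ``cuts`` the m+1 cut
    columns (left margin, m−1 interior midpoints, right margin), all
    0-based; ``margin`` is D_I, half the largest adjacent-peak spacing.
    """

    peak_cols: tuple[int, ...]
    cuts: tuple[int, ...]
    margin: float
    n_cols: int

    @property
    def n_plants(self) -> int:
        return len(self.peak_cols)

    def plant_slices(self) -> list[tuple[int, int]]:
        """Column interval [left, right] for each plant."""
        return [(self.cuts[j], self.cuts[j + 1]) for j in range(self.n_plants)]


def column_cut(
    band: np.ndarray,
    rel_threshold: float = 0.20,
    min_gap: int = 50,
    power: float = 2.0,
) -> ColumnCutResult:
    """Split a front-row band into individual plants.

    The column-mean profile is raised to ``power`` (default squared,
    which magnifies peak maxima relative to the inter-plant troughs),
    peak segments are called at ``rel_threshold`` of the maximum with
    runs < ``min_gap`` columns apart merged, and each segment's argmax
    becomes a plant peak.  Cuts between adjacent plants sit at the
    floor of the midpoint of their peaks; the outer margins sit D_I
    columns outside the first and last peaks, where D_I is half the
    largest adjacent-peak spacing (for a single plant, the width of its
    above-threshold segment), clipped to the band.
    """
    profile = column_profile(band)
    if profile.max() <= 0:
        raise ValueError("zero band: no plant pixels in the front-row band")
    transformed = profile**power
    segs = call_peak_segments(transformed, PeakParams(rel_threshold, min_gap))
    peaks = list(segs.peak_indices)
    m = len(peaks)
    n_cols = profile.size
    if m == 1:
        start, end = segs.segments[0]
        width = end - start + 1
        d_i = float(width)
    else:
        spacings = np.diff(peaks)
        d_i = float(spacings.max()) / 2.0
    interior = [int((peaks[j] + peaks[j + 1]) // 2) for j in range(m - 1)]
    left = max(int(np.floor(peaks[0] - d_i)), 0)
    right = min(int(np.ceil(peaks[-1] + d_i)), n_cols - 1)
    cuts = [left] + interior + [right]
    return ColumnCutResult(
        peak_cols=tuple(int(p) for p in peaks),
        cuts=tuple(cuts),
        margin=d_i,
        n_cols=n_cols,
    )


def cuts_from_peaks(peaks: np.ndarray, n_cols: int) -> tuple[tuple[int, ...], float]:
    """Cut columns implied by a set of plant peak columns.

    Same midpoint/margin geometry as :func:`column_cut`, for use when
    peaks come from elsewhere (e.g. stabilized across a time series).
    """
    p = [int(round(v)) for v in np.asarray(peaks, dtype=np.float64)]
    if len(p) == 0:
        raise ValueError("need at least one peak")
    if len(p) == 1:
        d_i = min(p[0], n_cols - 1 - p[0], n_cols // 4) or 1
        d_i = float(d_i)
    else:
        d_i = float(np.diff(p).max()) / 2.0
    interior = [int((p[j] + p[j + 1]) // 2) for j in range(len(p) - 1)]
    left = max(int(np.floor(p[0] - d_i)), 0)
    right = min(int(np.ceil(p[-1] + d_i)), n_cols - 1)
    return tuple([left] + interior + [right]), d_i
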