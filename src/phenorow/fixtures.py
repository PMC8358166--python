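"""Synthetic greenhouse/field imagery with exact ground truth.

Real side-view phenotyping data (camera-per-row field installations
photographing maize every 15 minutes, plus imaging-chamber greenhouse
photos) is large and rarely shareable, so this module renders small
synthetic stand-ins with known truth for every downstream stage:

* greenhouse scenes — a green plant silhouette (stem plus elliptical
  leaf blobs) on a near-uniform pale background, the input to K-means
  training-set construction;
* field scenes — a front row of plants on a common baseline, a second
  row of plants behind it, textured dirt/sky/equipment/shadow
  background, the input to segmentation and plant isolation;
* camera time series — field scenes with logistic plant growth, small
  horizontal camera jitter, occasional plant dropout, and an onset
  time after which the front and back rows merge vertically;
* height series — noisy observations of a known nondecreasing curve,
  the input to growth-curve fitting.

Silhouettes are deliberately schematic: the downstream algorithms only
require column-peaked, row-banded green structures, not realism.  All
randomness in a scene flows from its single seed, so outputs are
bit-identical for a fixed seed.  Colors are chosen so that plant and
background populations are separated in green contrast — the property
the real pipeline relies on — with field plant color deliberately
offset from greenhouse plant color to exercise the domain transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _ellipse

from .imgio import save_image, save_mask


def _gc(rgb) -> float:
    r, g, b = rgb
    return (-r + 2.0 * g - b) / 6.0


# ---------------------------------------------------------------------------
# greenhouse scenes


@dataclass
class GreenhouseConfig:
    height: int = 200
    width: int = 200
    plant_rgb: tuple[float, float, float] = (0.16, 0.55, 0.20)
    background_rgb: tuple[float, float, float] = (0.82, 0.82, 0.78)
    plant_noise: float = 0.03
    background_noise: float = 0.02
    n_leaves: int = 4

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError(f"degenerate size {self.height}×{self.width}; need ≥ 64×64")
        if _gc(self.plant_rgb) - _gc(self.background_rgb) < 0.05:
            raise ValueError(
                "plant and background color distributions overlap in green contrast"
            )


@dataclass
class GreenhouseScene:
    image: np.ndarray
    truth_mask: np.ndarray
    seed: int


def _draw_plant(
    shape: tuple[int, int],
    base_row: int,
    center_col: int,
    height: int,
    rng: np.random.Generator,
    stem_halfwidth: int,
    leaf_r: int,
    leaf_c: int,
    n_leaves: int,
    max_halfwidth: int | None = None,
) -> np.ndarray:
    """Render one schematic plant silhouette: stem + leaf ellipses.

    The silhouette's row extent is exactly [base_row − height, base_row]
    (the stem guarantees both extremes; leaves are clipped to it).
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    top = base_row - height
    if top < 0:
        raise ValueError(f"plant of height {height} does not fit above row {base_row}")
    c0 = max(center_col - stem_halfwidth, 0)
    c1 = min(center_col + stem_halfwidth, w - 1)
    mask[top : base_row + 1, c0 : c1 + 1] = True
    # leafy tip: young leaves wrap the top of the stalk, widening it
    tip_r = max(leaf_r // 2, 2)
    rr, ccs = _ellipse(top + tip_r, center_col, tip_r, max(int(0.8 * leaf_c), 3), shape=shape)
    keep = (rr >= top) & (rr <= base_row)
    if max_halfwidth is not None:
        keep &= np.abs(ccs - center_col) <= max_halfwidth
    mask[rr[keep], ccs[keep]] = True
    for _ in range(n_leaves):
        attach = int(rng.uniform(top + 0.15 * height, top + 0.80 * height))
        side = 1 if rng.random() < 0.5 else -1
        cc = center_col + side * int(rng.uniform(0.6, 1.2) * leaf_c)
        tilt = side * rng.uniform(0.3, 0.9)
        rr, ccs = _ellipse(attach, cc, leaf_r, leaf_c, shape=shape, rotation=tilt)
        keep = (rr >= top) & (rr <= base_row)
        if max_halfwidth is not None:
            keep &= np.abs(ccs - center_col) <= max_halfwidth
        mask[rr[keep], ccs[keep]] = True
    return mask


def make_greenhouse_scene(
    config: GreenhouseConfig | None = None, seed: int = 0
) -> GreenhouseScene:
    """Render a greenhouse scene: plant silhouette on a pale background.

    The truth mask marks exactly the silhouette.  A one-pixel blended
    "edge" ring is rendered just outside the silhouette (mimicking the
    soft plant/background boundary that K-means isolates as a third
    class); those ring pixels are background in the truth mask.
    """
    cfg = config or GreenhouseConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    scale = min(h, w) / 200.0
    base = int(0.9 * h)
    center = int(w / 2 + rng.uniform(-0.08, 0.08) * w)
    height_px = int(rng.uniform(0.60, 0.75) * h)
    mask = _draw_plant(
        (h, w),
        base,
        center,
        height_px,
        rng,
        stem_halfwidth=max(int(6 * scale), 3),
        leaf_r=max(int(9 * scale), 5),
        leaf_c=max(int(22 * scale), 10),
        n_leaves=cfg.n_leaves,
    )
    edge = ndimage.binary_dilation(mask, np.ones((3, 3), bool)) & ~mask

    img = np.empty((h, w, 3))
    img[:] = cfg.background_rgb
    img += rng.normal(0.0, cfg.background_noise, size=img.shape)
    plant = np.asarray(cfg.plant_rgb) + rng.normal(0.0, cfg.plant_noise, size=(h, w, 3))
    img[mask] = plant[mask]
    blend = 0.45 * np.asarray(cfg.plant_rgb) + 0.55 * np.asarray(cfg.background_rgb)
    img[edge] = blend + rng.normal(0.0, cfg.background_noise, size=(h, w, 3))[edge]
    img = np.clip(img, 0.0, 1.0)
    return GreenhouseScene(image=img, truth_mask=mask.astype(np.uint8), seed=seed)


# ---------------------------------------------------------------------------
# field scenes


@dataclass
class FieldConfig:
    height: int = 750
    width: int = 1000
    n_plants: int = 6
    heights: list[int] | None = None  # pixels; default drawn in [0.6, 1]·h_max
    h_max_frac: float = 0.30  # tallest plant as a fraction of image height
    base_row_frac: float = 0.88
    horizon_frac: float = 0.30
    margin: int = 80  # columns kept free at both sides
    min_gap: int | None = None  # center-to-center spacing; default fills the width
    stem_halfwidth: int = 5
    max_halfwidth: int = 28
    plant_rgb: tuple[float, float, float] = (0.20, 0.52, 0.16)
    back_plant_rgb: tuple[float, float, float] = (0.30, 0.52, 0.24)
    ground_rgb: tuple[float, float, float] = (0.45, 0.35, 0.25)
    sky_rgb: tuple[float, float, float] = (0.72, 0.78, 0.84)
    plant_noise: float = 0.03
    background_noise: float = 0.03
    back_row: bool = True
    textures: bool = True

    def validate(self) -> None:
        if self.n_plants < 1:
            raise ValueError("need at least one plant")
        if self.height < 64 or self.width < 64:
            raise ValueError(f"degenerate size {self.height}×{self.width}")
        spacing = self.spacing()
        needed = 2 * self.margin + (self.n_plants - 1) * spacing
        if needed > self.width:
            raise ValueError(
                f"{self.n_plants} plants at spacing {spacing} do not fit in "
                f"width {self.width}"
            )
        h_max = int(self.h_max_frac * self.height)
        if self.heights is not None:
            if len(self.heights) != self.n_plants:
                raise ValueError("heights must have one entry per plant")
            if min(self.heights) <= 0 or max(self.heights) > h_max:
                raise ValueError(f"heights must be in (0, {h_max}]")

    def spacing(self) -> int:
        if self.min_gap is not None:
            return self.min_gap
        if self.n_plants == 1:
            return 0
        return (self.width - 2 * self.margin) // (self.n_plants - 1)


@dataclass
class FieldScene:
    image: np.ndarray
    truth_mask: np.ndarray
    front_row_band: tuple[int, int]  # row interval containing front-row plants
    plant_centers: list[int]  # stem center columns, strictly increasing
    plant_heights_px: list[int]  # row-extent (bottom − top) per rendered plant
    seed: int
    base_row: int = 0
    visible: list[bool] = dc_field(default_factory=list)


def _paint_background(img, cfg: FieldConfig, rng, horizon: int) -> None:
    h, w, _ = img.shape
    img[:horizon] = cfg.sky_rgb
    img[horizon:] = cfg.ground_rgb
    if cfg.textures:
        n_patches = max(6, (h * w) // 20000)
        palette = [
            (0.55, 0.55, 0.55),  # poles / heat shields
            (0.62, 0.58, 0.48),  # dry dirt
            (0.25, 0.20, 0.15),  # shadow
            (0.38, 0.30, 0.22),  # wet dirt
        ]
        for _ in range(n_patches):
            color = palette[rng.integers(len(palette))]
            pr = int(rng.uniform(horizon, h - 1))
            pc = int(rng.uniform(0, w - 1))
            rr, cc = _ellipse(
                pr, pc, int(rng.uniform(4, 0.05 * h) + 2), int(rng.uniform(6, 0.08 * w) + 2),
                shape=(h, w), rotation=rng.uniform(-1.0, 1.0),
            )
            img[rr, cc] = color
        # a couple of vertical poles
        for _ in range(2):
            pc = int(rng.uniform(0.05 * w, 0.95 * w))
            img[horizon - h // 20 : h, pc : pc + max(2, w // 300)] = (0.55, 0.55, 0.55)
    img += rng.normal(0.0, cfg.background_noise, size=img.shape)


def make_field_scene(
    config: FieldConfig | None = None,
    seed: int = 0,
    _jitter: int = 0,
    _heights_override: list[int] | None = None,
    _visible: list[bool] | None = None,
    _back_row_bottom: int | None = None,
) -> FieldScene:
    """Render a field scene: a front row of plants on noisy background.

    Ground truth is recorded as rendered: ``plant_heights_px[j]`` equals
    plant j's mask row extent exactly, and ``plant_centers`` are the
    stem center columns.  Keyword-only underscore parameters are used by
    :func:`make_camera_series` to impose jitter, growth, dropout and
    row overlap while keeping single-scene rendering deterministic.
    """
    cfg = config or FieldConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    horizon = int(cfg.horizon_frac * h)
    base = int(cfg.base_row_frac * h)
    h_max = int(cfg.h_max_frac * h)
    spacing = cfg.spacing()

    # one genotype per row: sibling plants have similar heights
    heights = _heights_override or cfg.heights
    if heights is None:
        heights = [int(rng.uniform(0.85, 1.0) * h_max) for _ in range(cfg.n_plants)]
    centers = [cfg.margin + j * spacing + _jitter for j in range(cfg.n_plants)]
    if cfg.n_plants == 1:
        centers = [w // 2 + _jitter]
    centers = [int(np.clip(c, cfg.max_halfwidth, w - 1 - cfg.max_halfwidth)) for c in centers]
    visible = list(_visible) if _visible is not None else [True] * cfg.n_plants

    img = np.empty((h, w, 3))
    _paint_background(img, cfg, rng, horizon)

    mask = np.zeros((h, w), dtype=bool)
    scale = min(h, w) / 750.0
    leaf_r = max(int(14 * scale), 4)
    leaf_c = max(int(26 * scale), 6)

    # back row of smaller plants (always above the front-row band)
    if cfg.back_row:
        front_top_min = base - max(heights)
        # clearance must exceed the row-smoother's half window, or the two
        # rows' profile peaks merge into one band
        clearance = max(24, h // 25)
        back_bottom = (
            _back_row_bottom if _back_row_bottom is not None else front_top_min - clearance
        )
        back_top = max(back_bottom - int(0.08 * h) - 20, horizon + 2)
        if back_bottom > back_top:
            n_back = max(cfg.n_plants + 2, 6)
            back_rng = np.random.default_rng(seed + 7919)
            for jb in range(n_back):
                cb = int((jb + 0.5) * w / n_back + back_rng.uniform(-0.02, 0.02) * w)
                hb = back_bottom - back_top
                bmask = _draw_plant(
                    (h, w), back_bottom, int(np.clip(cb, 5, w - 6)), hb, back_rng,
                    stem_halfwidth=max(cfg.stem_halfwidth // 2, 1),
                    leaf_r=max(leaf_r // 2, 2), leaf_c=max(leaf_c // 2, 3),
                    n_leaves=2, max_halfwidth=max(cfg.max_halfwidth // 2, 4),
                )
                mask |= bmask

    # front row
    for j, (c, hp) in enumerate(zip(centers, heights)):
        if not visible[j]:
            continue
        pmask = _draw_plant(
            (h, w), base, c, hp, rng,
            stem_halfwidth=cfg.stem_halfwidth, leaf_r=leaf_r, leaf_c=leaf_c,
            n_leaves=4, max_halfwidth=cfg.max_halfwidth,
        )
        mask |= pmask

    plant = np.asarray(cfg.plant_rgb) + rng.normal(0.0, cfg.plant_noise, size=(h, w, 3))
    if cfg.back_row:
        back_region = np.zeros((h, w), dtype=bool)
        back_region[: base - max(heights) + 1, :] = True
        back_px = mask & back_region
        plant[back_px] = np.asarray(cfg.back_plant_rgb) + rng.normal(
            0.0, cfg.plant_noise, size=(h, w, 3)
        )[back_px]
    img[mask] = plant[mask]
    img = np.clip(img, 0.0, 1.0)

    return FieldScene(
        image=img,
        truth_mask=mask.astype(np.uint8),
        front_row_band=(base - max(heights), base),
        plant_centers=centers,
        plant_heights_px=list(heights),
        seed=seed,
        base_row=base,
        visible=visible,
    )


def background_crops(
    scene: FieldScene, n_crops: int = 6, size: tuple[int, int] = (40, 60), seed: int = 0
) -> list[np.ndarray]:
    """Plant-free rectangular snippets of a field scene.

    Random windows are sampled and kept only if they contain no truth
    plant pixel — the synthetic analogue of hand-cropping background
    pieces (dirt, sky, shadows, equipment) out of field photos.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.truth_mask.shape
    ch, cw = size
    crops: list[np.ndarray] = []
    attempts = 0
    while len(crops) < n_crops and attempts < 200 * n_crops:
        attempts += 1
        r = int(rng.integers(0, h - ch))
        c = int(rng.integers(0, w - cw))
        if scene.truth_mask[r : r + ch, c : c + cw].sum() == 0:
            crops.append(scene.image[r : r + ch, c : c + cw].copy())
    if not crops:
        raise RuntimeError("could not find any plant-free crop window")
    return crops


# ---------------------------------------------------------------------------
# camera time series


@dataclass
class CameraSeriesConfig:
    n_times: int = 24
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    growth_rate: float = 0.45  # logistic rate per frame unit (rescaled)
    start_frac: float = 0.40  # initial height as a fraction of final
    midpoint_frac: float = 0.40  # logistic midpoint as a fraction of the series
    jitter_sd: float = 0.0  # columns, per-frame horizontal camera shift
    dropout_prob: float = 0.0  # per (frame, plant) occlusion probability
    overlap_onset: int | None = None  # frame index; None = never

    def validate(self) -> None:
        if self.n_times < 10:
            raise ValueError("need at least 10 frames")
        if self.overlap_onset is not None and not (0 <= self.overlap_onset <= self.n_times):
            raise ValueError(f"overlap_onset must be in [0, {self.n_times}]")


@dataclass
class CameraSeries:
    scenes: list[FieldScene]
    times: np.ndarray
    true_heights: np.ndarray  # n_times × n_plants, nondecreasing per plant
    jitter: np.ndarray  # per-frame column shift of the whole front row
    overlap_onset: int  # == n_times when rows never overlap
    dropout: set[tuple[int, int]]  # (frame, plant) pairs occluded
    config: CameraSeriesConfig


def make_camera_series(config: CameraSeriesConfig | None = None, seed: int = 0) -> CameraSeries:
    """Render a camera's time series of field scenes with known growth.

    Per-plant heights follow a rounded logistic curve (forced
    nondecreasing); the whole front row shifts horizontally by a
    per-frame integer jitter; occluded (frame, plant) pairs are simply
    not rendered; from ``overlap_onset`` onward the back row is pulled
    down to touch the front row's top, so the two rows have no vertical
    gap and the front-row band height jumps.
    """
    cfg = config or CameraSeriesConfig()
    cfg.validate()
    fcfg = cfg.field
    fcfg.validate()
    rng = np.random.default_rng(seed)
    n_t, n_p = cfg.n_times, fcfg.n_plants
    h_max = int(fcfg.h_max_frac * fcfg.height)
    base = int(fcfg.base_row_frac * fcfg.height)

    final = rng.uniform(0.85, 1.0, size=n_p) * h_max
    start = cfg.start_frac * final
    tt = np.arange(n_t)
    mid = cfg.midpoint_frac * n_t
    logistic = 1.0 / (1.0 + np.exp(-cfg.growth_rate * (tt[:, None] - mid)))
    l0 = 1.0 / (1.0 + np.exp(cfg.growth_rate * mid))
    l1 = 1.0 / (1.0 + np.exp(-cfg.growth_rate * (n_t - 1 - mid)))
    frac = (logistic - l0) / (l1 - l0)
    true_heights = np.round(start[None, :] + frac * (final - start)[None, :]).astype(int)
    true_heights = np.maximum.accumulate(true_heights, axis=0)

    jitter = np.round(rng.normal(0.0, cfg.jitter_sd, size=n_t)).astype(int)
    dropout = {
        (int(t), int(j))
        for t in range(n_t)
        for j in range(n_p)
        if rng.random() < cfg.dropout_prob
    }
    onset = cfg.overlap_onset if cfg.overlap_onset is not None else n_t

    # fixed back-row bottom: a safe gap below the tallest pre-onset top
    ref = max(onset - 1, 0) if onset > 0 else 0
    top_ref = base - int(true_heights[min(ref, n_t - 1)].max())
    back_bottom_fixed = top_ref - max(24, fcfg.height // 25)

    scenes = []
    for t in range(n_t):
        heights_t = [int(v) for v in true_heights[t]]
        visible = [(t, j) not in dropout for j in range(n_p)]
        if t >= onset:
            back_bottom = base - max(heights_t)  # touch the front row: zero gap
        else:
            back_bottom = back_bottom_fixed
        scene = make_field_scene(
            fcfg,
            seed=int((seed * 100003 + t) % (2**31 - 1)),
            _jitter=int(jitter[t]),
            _heights_override=heights_t,
            _visible=visible,
            _back_row_bottom=back_bottom,
        )
        scenes.append(scene)

    return CameraSeries(
        scenes=scenes,
        times=tt.astype(float),
        true_heights=true_heights,
        jitter=jitter,
        overlap_onset=onset,
        dropout=dropout,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# simulated height series


@dataclass
class SimulatedHeightSeries:
    t: np.ndarray
    y: np.ndarray
    mu: np.ndarray  # true nondecreasing mean
    noise_sd: float
    outlier_indices: tuple[int, ...]
    seed: int


def logistic_mu(t: np.ndarray, low: float, high: float, rate: float, midpoint: float) -> np.ndarray:
    """A logistic growth curve on an arbitrary time grid."""
    return low + (high - low) / (1.0 + np.exp(-rate * (t - midpoint)))


def simulate_height_series(
    n: int = 120,
    low: float = 50.0,
    high: float = 250.0,
    rate: float = 10.0,
    midpoint: float = 0.45,
    noise_sd: float = 10.0,
    outliers: dict[int, float] | None = None,
    seed: int = 0,
    mu: np.ndarray | None = None,
) -> SimulatedHeightSeries:
    """Noisy observations of a known nondecreasing growth curve.

    ``y = mu(t) + N(0, noise_sd²)`` on an equispaced [0, 1] time grid,
    with optional gross outliers added at stated indices.  A custom
    ``mu`` may be passed; it must be nondecreasing.
    """
    t = np.linspace(0.0, 1.0, n)
    if mu is None:
        mu = logistic_mu(t, low, high, rate, midpoint)
    else:
        mu = np.asarray(mu, dtype=np.float64)
        if mu.size != n:
            raise ValueError("mu must have length n")
    if np.any(np.diff(mu) < -1e-12):
        raise ValueError("mu must be nondecreasing")
    rng = np.random.default_rng(seed)
    y = mu + rng.normal(0.0, noise_sd, size=n)
    outliers = outliers or {}
    for idx, mag in outliers.items():
        if not 0 <= idx < n:
            raise ValueError(f"outlier index {idx} outside [0, {n})")
        y[idx] += mag
    return SimulatedHeightSeries(
        t=t, y=y, mu=mu, noise_sd=noise_sd,
        outlier_indices=tuple(sorted(outliers)), seed=seed,
    )


# ---------------------------------------------------------------------------
# writing fixtures to disk


def write_greenhouse_scene(scene: GreenhouseScene, outdir, stem: str = "greenhouse") -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    save_image(os.path.join(outdir, f"{stem}.png"), scene.image)
    save_mask(os.path.join(outdir, f"{stem}_mask.png"), scene.truth_mask)
    with open(os.path.join(outdir, f"{stem}.json"), "w") as fh:
        json.dump({"seed": scene.seed}, fh)


def write_field_scene(scene: FieldScene, outdir, stem: str = "field") -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    save_image(os.path.join(outdir, f"{stem}.png"), scene.image)
    save_mask(os.path.join(outdir, f"{stem}_mask.png"), scene.truth_mask)
    truth = {
        "seed": scene.seed,
        "front_row_band": list(scene.front_row_band),
        "plant_centers": [int(c) for c in scene.plant_centers],
        "plant_heights_px": [int(v) for v in scene.plant_heights_px],
        "base_row": scene.base_row,
        "visible": list(scene.visible),
    }
    with open(os.path.join(outdir, f"{stem}.json"), "w") as fh:
        json.dump(truth, fh, indent=1)


def write_camera_series(series: CameraSeries, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    for t, scene in enumerate(series.scenes):
        write_field_scene(scene, outdir, stem=f"frame{t:04d}")
    truth = {
        "times": series.times.tolist(),
        "true_heights": series.true_heights.tolist(),
        "jitter": series.jitter.tolist(),
        "overlap_onset": int(series.overlap_onset),
        "dropout": sorted([list(p) for p in series.dropout]),
    }
    with open(os.path.join(outdir, "series.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
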