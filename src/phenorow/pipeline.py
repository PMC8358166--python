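"""End-to-end orchestration: images in, growth curves out.

A single config drives the seven stages — training-set construction,
classifier training, segmentation, front-row isolation, per-plant
height measurement, time-series refinement, growth-curve fitting —
writing every intermediate artifact into a run directory together with
a manifest (stage, parameters, seed, sha256 per file).  Stages only
read paths declared in the config, so a run is reproducible and
hermetic; with a fixed seed all non-training artifacts are
bit-identical across reruns, and training metrics are logged so that
backend-induced float variation is visible.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .growth import CurveConfig, fit_growth_curve
from .imgio import load_image, save_mask
from .segmentation import SegmenterConfig, predict_mask, train_segmenter
from .series import measure_series
from .training_data import (
    assemble_training_set,
    build_feature_table,
    kmeans_plant_mask,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    greenhouse_dir: str
    background_dir: str
    series_dir: str
    seed: int = 0
    rescale: tuple[int, int] | None = None  # (width, height), e.g. (1000, 750)
    kmeans_k: int = 3
    max_plant_pixels_per_image: int = 6000
    max_background_pixels_per_image: int = 6000
    holdout_frac: float = 0.01
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    row_params: dict = field(default_factory=dict)
    col_params: dict = field(default_factory=dict)
    expected_plant_count: int | None = None
    changepoint_penalty: float | None = None
    curve: CurveConfig = field(default_factory=CurveConfig)
    min_curve_points: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "segmenter" in raw:
            raw["segmenter"] = SegmenterConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["segmenter"].items()
            })
        if "curve" in raw:
            raw["curve"] = CurveConfig(**raw["curve"])
        if raw.get("rescale") is not None:
            raw["rescale"] = tuple(raw["rescale"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("greenhouse_dir", "background_dir", "series_dir"):
            path = getattr(self, name)
            if not os.path.isdir(path):
                raise FileNotFoundError(f"{name} does not exist: {path}")
            if not _list_images(path):
                raise FileNotFoundError(f"{name} contains no PNG/JPEG images: {path}")


def _list_images(directory: str) -> list[str]:
    paths: list[str] = []
    for pat in ("*.png", "*.jpg", "*.jpeg"):
        paths.extend(glob.glob(os.path.join(directory, pat)))
    return sorted(p for p in paths if not p.endswith("_mask.png"))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: str, cfg: PipelineConfig):
        self.run_dir = run_dir
        self.entries: list[dict] = []
        self.meta = {"seed": cfg.seed, "rescale": cfg.rescale}

    def add(self, stage: str, path: str, inputs: list[str] | None = None) -> None:
        self.entries.append(
            {
                "stage": stage,
                "path": os.path.relpath(path, self.run_dir),
                "inputs": inputs or [],
                "sha256": _sha256(path),
            }
        )

    def write(self) -> None:
        with open(os.path.join(self.run_dir, "manifest.json"), "w") as fh:
            json.dump({"meta": self.meta, "artifacts": self.entries}, fh, indent=1)


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest = _Manifest(out_dir, cfg)
    rng = np.random.default_rng(cfg.seed)

    # stage 1: self-supervised training set
    logger.info("stage build-train")
    plant_tabs, bg_tabs = [], []
    for path in _list_images(cfg.greenhouse_dir):
        img = load_image(path, rescale=cfg.rescale)
        mask = kmeans_plant_mask(img, k=cfg.kmeans_k, seed=cfg.seed)
        rows, cols = np.nonzero(mask)
        if len(rows) > cfg.max_plant_pixels_per_image:
            sel = rng.choice(len(rows), cfg.max_plant_pixels_per_image, replace=False)
            rows, cols = rows[sel], cols[sel]
        plant_tabs.append(
            build_feature_table(img, list(zip(rows, cols)), 1, os.path.basename(path))
        )
        logger.info("  %s: %d plant pixels", os.path.basename(path), len(rows))
    for path in _list_images(cfg.background_dir):
        img = load_image(path)
        h, w, _ = img.shape
        coords = [(r, c) for r in range(h) for c in range(w)]
        if len(coords) > cfg.max_background_pixels_per_image:
            sel = rng.choice(len(coords), cfg.max_background_pixels_per_image, replace=False)
            coords = [coords[i] for i in sel]
        bg_tabs.append(build_feature_table(img, coords, 0, os.path.basename(path)))
    train, val = assemble_training_set(
        pd.concat(plant_tabs, ignore_index=True),
        pd.concat(bg_tabs, ignore_index=True),
        holdout_frac=cfg.holdout_frac,
        seed=cfg.seed,
    )
    train_csv = os.path.join(out_dir, "train.csv")
    val_csv = os.path.join(out_dir, "val.csv")
    write_table(train, train_csv)
    write_table(val, val_csv)
    manifest.add("build-train", train_csv)
    manifest.add("build-train", val_csv)

    # stage 2: train the pixel classifier
    logger.info("stage train (%d rows)", len(train))
    model = train_segmenter(train, val, cfg.segmenter)
    model_dir = os.path.join(out_dir, "model")
    model.save(model_dir)
    manifest.add("train", os.path.join(model_dir, "weights.npz"), [train_csv])
    manifest.add("train", os.path.join(model_dir, "config.json"))

    # stage 3: segment the series frames
    logger.info("stage segment")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(mask_dir, exist_ok=True)
    frame_paths = _list_images(cfg.series_dir)
    masks = []
    for path in frame_paths:
        img = load_image(path, rescale=cfg.rescale)
        mask = predict_mask(model, img)
        masks.append(mask)
        out_path = os.path.join(mask_dir, os.path.basename(path).rsplit(".", 1)[0] + "_mask.png")
        save_mask(out_path, mask)
        manifest.add("segment", out_path, [path])
        logger.info("  %s: %d plant pixels", os.path.basename(path), int(mask.sum()))

    # stages 4–6: isolation, measurement, series refinement
    logger.info("stage series (%d frames)", len(masks))
    result = measure_series(
        masks,
        expected_count=cfg.expected_plant_count,
        row_params=cfg.row_params,
        col_params=cfg.col_params,
        changepoint_penalty=cfg.changepoint_penalty,
    )
    series_json = os.path.join(out_dir, "series.json")
    with open(series_json, "w") as fh:
        json.dump(
            {
                "changepoint_index": result.changepoint_index,
                "band_heights": result.band_heights,
                "plant_counts": result.plant_counts,
                "modal_count": result.modal_count,
                "valid_frames": result.valid_frames,
                "stabilized_peaks": result.stabilized_peaks.tolist(),
                "skipped": result.skipped,
                "frames": [os.path.basename(p) for p in frame_paths],
            },
            fh,
            indent=1,
        )
    manifest.add("series", series_json)
    heights_csv = os.path.join(out_dir, "heights.csv")
    rows = [
        {"plant_id": j, "frame": i, "height_px": h}
        for j, hs in result.heights.items()
        for i, h in hs
    ]
    pd.DataFrame(rows, columns=["plant_id", "frame", "height_px"]).to_csv(heights_csv, index=False)
    manifest.add("measure", heights_csv)

    # stage 7: growth curves
    logger.info("stage curve")
    curve_dir = os.path.join(out_dir, "curves")
    os.makedirs(curve_dir, exist_ok=True)
    curves = {}
    for j, hs in result.heights.items():
        if len(hs) < max(cfg.min_curve_points, 10):
            logger.warning("plant %d: only %d heights, skipping curve", j, len(hs))
            continue
        t = np.array([i for i, _ in hs], dtype=float)
        y = np.array([h for _, h in hs], dtype=float)
        try:
            fit = fit_growth_curve(t, y, cfg.curve)
        except ValueError as exc:
            logger.warning("plant %d: curve fit failed (%s)", j, exc)
            continue
        path = os.path.join(curve_dir, f"plant{j}.csv")
        pd.DataFrame({"time": fit.grid_times, "fitted": fit.fitted, "unconstrained": fit.unconstrained}).to_csv(
            path, index=False
        )
        manifest.add("curve", path, [heights_csv])
        curves[j] = {
            "r_squared": fit.r_squared,
            "removed": list(fit.removed_indices),
            "h_r": fit.smoother_bandwidth,
            "h_d": fit.inversion_bandwidth,
            "n_points": int(fit.t.size),
        }

    summary = {
        "n_frames": len(masks),
        "changepoint_index": result.changepoint_index,
        "modal_count": result.modal_count,
        "n_valid_frames": len(result.valid_frames),
        "curves": curves,
    }
    summary_json = os.path.join(out_dir, "summary.json")
    with open(summary_json, "w") as fh:
        json.dump(summary, fh, indent=1)
    manifest.add("curve", summary_json)
    manifest.write()
    return summary
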