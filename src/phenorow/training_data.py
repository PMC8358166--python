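"""Self-supervised construction of the pixel-level training set.

Plant-class pixels are harvested from clean-background greenhouse images
by K-means clustering of per-pixel RGB vectors: with two well separated
color populations the Euclidean metric isolates the plant silhouette
without any human labels.  Background-class pixels come from snippets
cropped out of field images that contain only background (dirt, sky,
equipment, shadows).  Each labeled pixel is described by the RGB values
of its 3×3 neighborhood — 27 features — so that a pixel classifier can
exploit the fact that plant and background pixels tend to be surrounded
by pixels of their own class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .imgio import as_float_image

#: Column names of a labeled feature table, in the canonical order.
FEATURE_COLUMNS = [f"f{i:02d}" for i in range(27)]
TABLE_COLUMNS = FEATURE_COLUMNS + ["label", "image_id", "row", "col"]


@dataclass(frozen=True)
class PixelSample:
    """A single labeled pixel: its location, color and class."""

    image_id: str
    row: int
    col: int
    rgb: tuple[float, float, float]
    label: int  # 0 = background, 1 = plant


def green_contrast(image: np.ndarray) -> np.ndarray:
    """Green-contrast intensity map, weights (−1/6, 2/6, −1/6) on (R, G, B).

    The linear combination (−R + 2G − B)/6 emphasizes vegetation: pure
    green maps to 1/3, any gray to 0.  Values lie in [−1/3, 1/3] for
    inputs in [0, 1].
    """
    arr = as_float_image(image)
    return (-arr[..., 0] + 2.0 * arr[..., 1] - arr[..., 2]) / 6.0


def kmeans_plant_mask(image: np.ndarray, k: int = 3, seed: int = 0) -> np.ndarray:
    """Cluster pixels by RGB K-means and return the plant-body mask.

    Clusters are ranked by the green contrast of their centroids; the
    top-ranked cluster is the plant body.  With ``k=3`` the middle
    cluster captures the blended plant/background boundary (the "edge")
    and is discarded, so only the plant-body cluster is returned.

    Parameters
    ----------
    image
        Greenhouse RGB image with a near-uniform background.
    k
        Number of clusters, 2 or 3.
    seed
        Initialization seed (k-means++ with 10 restarts).
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    arr = as_float_image(image)
    h, w, _ = arr.shape
    x = arr.reshape(-1, 3)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"image has fewer than {k} distinct colors")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    centers = km.cluster_centers_
    contrast = (-centers[:, 0] + 2.0 * centers[:, 1] - centers[:, 2]) / 6.0
    plant_cluster = int(np.argmax(contrast))
    mask = (labels == plant_cluster).reshape(h, w)
    if not mask.any():
        raise RuntimeError(
            "plant cluster is empty; cluster means (RGB) were "
            + ", ".join(str(tuple(np.round(c, 4))) for c in centers)
        )
    return mask.astype(np.uint8)


def kmeans_plant_pixels(
    image: np.ndarray, k: int = 3, seed: int = 0, image_id: str = "greenhouse"
) -> list[PixelSample]:
    """Plant-class pixel samples from a greenhouse image via K-means."""
    mask = kmeans_plant_mask(image, k=k, seed=seed)
    arr = as_float_image(image)
    rows, cols = np.nonzero(mask)
    return [
        PixelSample(image_id, int(r), int(c), tuple(arr[r, c]), 1)
        for r, c in zip(rows, cols)
    ]


def extract_background_pixels(
    crops: Sequence[np.ndarray], image_ids: Sequence[str] | None = None
) -> list[PixelSample]:
    """Label every pixel of every background crop as class 0."""
    if len(crops) == 0:
        raise ValueError("need at least one background crop")
    if image_ids is None:
        image_ids = [f"crop{i}" for i in range(len(crops))]
    samples: list[PixelSample] = []
    for crop, cid in zip(crops, image_ids):
        arr = as_float_image(crop)
        h, w, _ = arr.shape
        for r in range(h):
            for c in range(w):
                samples.append(PixelSample(cid, r, c, tuple(arr[r, c]), 0))
    return samples


def neighborhood_features(image: np.ndarray) -> np.ndarray:
    """27 features for every pixel: RGB of its 3×3 neighborhood.

    Raster order is fixed: neighborhood rows top→bottom, within each row
    left→right, channels (R, G, B) per pixel — so features 12–14 are the
    center pixel's own RGB.  Out-of-image neighbors of border pixels are
    filled by edge replication.

    Returns an H×W×27 array.
    """
    arr = as_float_image(image)
    padded = np.pad(arr, ((1, 1), (1, 1), (0, 0)), mode="edge")
    h, w, _ = arr.shape
    blocks = []
    for dr in range(3):
        for dc in range(3):
            blocks.append(padded[dr : dr + h, dc : dc + w, :])
    return np.concatenate(blocks, axis=2)


def build_feature_table(
    image: np.ndarray,
    pixels: Iterable[tuple[int, int]],
    label: int,
    image_id: str = "img",
) -> pd.DataFrame:
    """Labeled 27-feature rows for the given pixel coordinates.

    Raises if any coordinate lies outside the image.
    """
    arr = as_float_image(image)
    h, w, _ = arr.shape
    coords = np.asarray(list(pixels), dtype=np.int64)
    if coords.size == 0:
        coords = coords.reshape(0, 2)
    if coords.size and (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= h
        or coords[:, 1].max() >= w
    ):
        raise IndexError("pixel coordinates outside image bounds")
    feats = neighborhood_features(arr)[coords[:, 0], coords[:, 1], :] if coords.size else np.empty((0, 27))
    df = pd.DataFrame(feats, columns=FEATURE_COLUMNS)
    df["label"] = int(label)
    df["image_id"] = image_id
    df["row"] = coords[:, 0] if coords.size else np.array([], dtype=np.int64)
    df["col"] = coords[:, 1] if coords.size else np.array([], dtype=np.int64)
    return df


def feature_table_from_samples(
    images: dict[str, np.ndarray], samples: Sequence[PixelSample]
) -> pd.DataFrame:
    """Build one feature table from pixel samples spanning several images."""
    parts = []
    for image_id, image in images.items():
        for label in (0, 1):
            coords = [(s.row, s.col) for s in samples if s.image_id == image_id and s.label == label]
            if coords:
                parts.append(build_feature_table(image, coords, label, image_id))
    if not parts:
        raise ValueError("no samples matched the provided images")
    return pd.concat(parts, ignore_index=True)


def assemble_training_set(
    plant: pd.DataFrame,
    background: pd.DataFrame,
    holdout_frac: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle the two classes together and split off a validation set.

    ``holdout_frac`` of the rows (rounded up, so any positive fraction
    holds out at least one row; 0 holds out none) become the validation
    table.  Shuffling is deterministic in ``seed``.
    """
    if len(plant) == 0 or len(background) == 0:
        raise ValueError("both classes must be nonempty")
    full = pd.concat([plant, background], ignore_index=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(full))
    full = full.iloc[order].reset_index(drop=True)
    n_val = int(np.ceil(holdout_frac * len(full))) if holdout_frac > 0 else 0
    val = full.iloc[:n_val].reset_index(drop=True)
    train = full.iloc[n_val:].reset_index(drop=True)
    return train, val


def features_labels(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a labeled feature table into (n×27 features, n labels)."""
    x = table[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy(dtype=np.int64)
    return x, y


def write_table(table: pd.DataFrame, path) -> None:
    """Write a labeled feature table as CSV (round-trips exactly)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df[TABLE_COLUMNS]
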