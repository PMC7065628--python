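"""Featurizations of processed single-cell images.

Three representations feed the non-convolutional classifiers:

``pixels6724``
    The 82 x 82 intensity matrix flattened row-major into a 6724-vector.
``scalar2``
    Two scalars: cell size (pixel count of the mask) and total image
    intensity (sum over the full crop; zero padding contributes nothing).
``cp123``
    123 named morphology features in three groups — 18 shape/area,
    17 intensity-over-mask, and 88 texture statistics (11 Haralick
    co-occurrence statistics x distances {1, 3} x 4 offsets on the
    8-level-quantized mask bounding box).

Feature order is fixed and identical across cells, runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix
from skimage.measure import regionprops

from .preprocess import PAD_SIDE, ProcessedCell

__all__ = [
    "FeatureTable",
    "pixel_features",
    "scalar_features",
    "cp_features",
    "cp_feature_names",
    "build_feature_table",
    "FEATURE_SET_SIZES",
]

FEATURE_SET_SIZES = {"pixels6724": 6724, "scalar2": 2, "cp123": 123}

_GLCM_DISTANCES = (1, 3)
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_LEVELS = 8
_HARALICK_STATS = (
    "contrast", "dissimilarity", "homogeneity", "asm", "energy",
    "correlation", "entropy", "variance", "sum_average", "cluster_shade",
    "cluster_prominence",
)

_SHAPE_NAMES = (
    "area", "perimeter", "eccentricity", "solidity", "extent",
    "major_axis_length", "minor_axis_length", "orientation", "form_factor",
    "bbox_height", "bbox_width", "bbox_area", "equivalent_diameter",
    "convex_area", "euler_number", "aspect_ratio", "compactness",
    "feret_diameter_max",
)

_INTENSITY_NAMES = (
    "intensity_mean", "intensity_median", "intensity_std", "intensity_mad",
    "intensity_min", "intensity_max", "intensity_integrated",
    "intensity_q10", "intensity_q25", "intensity_q75", "intensity_q90",
    "mass_displacement", "edge_intensity_mean", "edge_intensity_std",
    "edge_intensity_min", "edge_intensity_max", "edge_intensity_integrated",
)


def cp_feature_names() -> list[str]:
    """The fixed, ordered list of the 123 morphology feature names."""
    names = [f"shape_{n}" for n in _SHAPE_NAMES]
    names += [f"{n}" for n in _INTENSITY_NAMES]
    for d in _GLCM_DISTANCES:
        for ai in range(len(_GLCM_ANGLES)):
            for stat in _HARALICK_STATS:
                names.append(f"texture_{stat}_d{d}_a{ai * 45}")
    assert len(names) == 123
    return names


def pixel_features(cell: ProcessedCell | np.ndarray) -> np.ndarray:
    """Row-major flattening of an 82 x 82 image into a 6724-vector."""
    img = cell.image if isinstance(cell, ProcessedCell) else np.asarray(cell)
    if img.shape != (PAD_SIDE, PAD_SIDE):
        raise ValueError(
            f"pixel features require a {PAD_SIDE}x{PAD_SIDE} image, "
            f"got {img.shape}")
    return img.astype(np.float64).ravel(order="C")


def scalar_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(mask pixel count, total image intensity) for one cell."""
    if mask is None:
        raise ValueError("scalar features require a cell mask")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("scalar features require a nonempty mask")
    return np.array([float(mask.sum()), float(np.asarray(image).sum())])


def _haralick_stats(P: np.ndarray) -> dict[str, float]:
    """Eleven co-occurrence statistics of one normalized symmetric GLCM."""
    levels = P.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(levels) * px).sum())
    mu_y = float((np.arange(levels) * py).sum())
    sd_x = float(np.sqrt(((np.arange(levels) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(levels) - mu_y) ** 2 * py).sum()))
    diff = i - j
    contrast = float((diff**2 * P).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    asm = float((P**2).sum())
    energy = float(np.sqrt(asm))
    if sd_x > 0 and sd_y > 0:
        correlation = float((((i - mu_x) * (j - mu_y) * P).sum())
                            / (sd_x * sd_y))
    else:
        correlation = 1.0  # constant texture: perfectly correlated
    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    mu = (mu_x + mu_y) / 2.0
    variance = float((((i - mu) ** 2) * P).sum())
    k = np.arange(2 * levels - 1)
    p_sum = np.zeros(2 * levels - 1)
    for kk in range(2 * levels - 1):
        p_sum[kk] = P[(i + j) == kk].sum()
    sum_average = float((k * p_sum).sum())
    shade_base = (i + j) - mu_x - mu_y
    cluster_shade = float(((shade_base**3) * P).sum())
    cluster_prominence = float(((shade_base**4) * P).sum())
    return {
        "contrast": contrast, "dissimilarity": dissimilarity,
        "homogeneity": homogeneity, "asm": asm, "energy": energy,
        "correlation": correlation, "entropy": entropy, "variance": variance,
        "sum_average": sum_average, "cluster_shade": cluster_shade,
        "cluster_prominence": cluster_prominence,
    }


def _texture_features(image: np.ndarray, mask: np.ndarray) -> list[float]:
    """88 Haralick statistics on the 8-level-quantized mask bounding box."""
    ys, xs = np.nonzero(mask)
    sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
    crop = np.asarray(image, dtype=float)[sl]
    crop_mask = mask[sl]
    vals = crop[crop_mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros_like(crop, dtype=np.uint8)
    if hi > lo:
        q_in = np.floor((crop - lo) / (hi - lo) * _GLCM_LEVELS)
        q = np.clip(q_in, 0, _GLCM_LEVELS - 1).astype(np.uint8)
    q[~crop_mask] = 0
    glcm = graycomatrix(q, distances=_GLCM_DISTANCES, angles=_GLCM_ANGLES,
                        levels=_GLCM_LEVELS, symmetric=True, normed=True)
    out = []
    for di in range(len(_GLCM_DISTANCES)):
        for ai in range(len(_GLCM_ANGLES)):
            stats = _haralick_stats(glcm[:, :, di, ai])
            out.extend(stats[s] for s in _HARALICK_STATS)
    return out


def cp_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The fixed 123-feature morphology vector for one cell.

    Degenerate masks (down to a single pixel) yield finite values by
    convention (eccentricity 0, perimeter 0) rather than failing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cp features require a nonempty mask")
    image = np.asarray(image, dtype=float)

    props = regionprops(mask.astype(np.uint8), intensity_image=image)[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    h = float(props.bbox[2] - props.bbox[0])
    w = float(props.bbox[3] - props.bbox[1])
    form_factor = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
    shape_vals = [
        area, perimeter, float(props.eccentricity), float(props.solidity),
        float(props.extent), major, minor, float(props.orientation),
        form_factor, h, w, h * w, float(props.equivalent_diameter_area),
        float(props.area_convex), float(props.euler_number),
        major / minor if minor > 0 else 1.0,
        perimeter**2 / area if area > 0 else 0.0,
        float(props.feret_diameter_max),
    ]

    vals = image[mask]
    ys, xs = np.nonzero(mask)
    total = float(vals.sum())
    if total > 0:
        com = (float((ys * image[mask]).sum()) / total,
               float((xs * image[mask]).sum()) / total)
    else:
        com = (float(ys.mean()), float(xs.mean()))
    centroid = (float(ys.mean()), float(xs.mean()))
    mass_disp = float(np.hypot(com[0] - centroid[0], com[1] - centroid[1]))
    eroded = ndimage.binary_erosion(mask)
    edge = mask & ~eroded
    if not edge.any():
        edge = mask
    evals = image[edge]
    intensity_vals = [
        float(vals.mean()), float(np.median(vals)), float(vals.std()),
        float(np.median(np.abs(vals - np.median(vals)))),
        float(vals.min()), float(vals.max()), total,
        float(np.quantile(vals, 0.10)), float(np.quantile(vals, 0.25)),
        float(np.quantile(vals, 0.75)), float(np.quantile(vals, 0.90)),
        mass_disp, float(evals.mean()), float(evals.std()),
        float(evals.min()), float(evals.max()), float(evals.sum()),
    ]

    out = np.array(shape_vals + intensity_vals
                   + _texture_features(image, mask))
    out[~np.isfinite(out)] = 0.0
    assert out.shape == (123,)
    return out


@dataclass
class FeatureTable:
    """A cells x features matrix with named columns and cell metadata."""

    feature_set_id: str
    values: pd.DataFrame          # index: cell id; columns: feature names
    meta: pd.DataFrame            # index: cell id; donor_id, label, aug tag

    def __post_init__(self) -> None:
        expected = FEATURE_SET_SIZES[self.feature_set_id]
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.feature_set_id} requires {expected} columns, "
                f"got {self.values.shape[1]}")
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return (self.meta["label"] == "activated").to_numpy(dtype=int)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        joined = pd.concat([self.meta, self.values], axis=1)
        # %.17g round-trips IEEE doubles exactly through text
        joined.to_csv(path, index_label="cell_id", float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"feature_set_id": self.feature_set_id}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        feature_set_id = json.loads(sidecar.read_text())["feature_set_id"]
        joined = pd.read_csv(path, index_col="cell_id",
                             float_precision="round_trip")
        meta_cols = [c for c in ("donor_id", "label", "augmentation_tag")
                     if c in joined.columns]
        return cls(feature_set_id=feature_set_id,
                   values=joined.drop(columns=meta_cols),
                   meta=joined[meta_cols])


def _cell_key(cell: ProcessedCell, i: int) -> str:
    base = cell.source_id or f"cell{i:05d}"
    return f"{base}__{cell.augmentation_tag}"


def build_feature_table(cells: list[ProcessedCell],
                        feature_set_id: str) -> FeatureTable:
    """Extract one feature set for every cell into a :class:`FeatureTable`.

    Cell ids must be unique (source id + augmentation tag); scalar2 and
    cp123 require cells to carry masks.
    """
    if feature_set_id not in FEATURE_SET_SIZES:
        raise ValueError(f"unknown feature set {feature_set_id!r}")
    ids = [_cell_key(c, i) for i, c in enumerate(cells)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids in dataset")

    if feature_set_id == "pixels6724":
        rows = [pixel_features(c) for c in cells]
        cols = [f"px_{r}_{c}" for r in range(PAD_SIDE) for c in range(PAD_SIDE)]
    elif feature_set_id == "scalar2":
        rows = [scalar_features(c.image, c.mask) for c in cells]
        cols = ["mask_size", "total_intensity"]
    else:
        rows = [cp_features(c.image, c.mask) for c in cells]
        cols = cp_feature_names()

    matrix = (np.asarray(rows, dtype=np.float64)
              if cells else np.empty((0, len(cols))))
    values = pd.DataFrame(
        matrix.reshape(len(cells), len(cols)),
        index=pd.Index(ids, name="cell_id"), columns=cols)
    meta = pd.DataFrame(
        {"donor_id": [c.donor_id for c in cells],
         "label": [c.label for c in cells],
         "augmentation_tag": [c.augmentation_tag for c in cells]},
        index=values.index)
    return FeatureTable(feature_set_id=feature_set_id, values=values,
                        meta=meta)
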