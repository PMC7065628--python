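"""Single-cell image preprocessing cascade.

Stages, in fixed order: segmentation of full-field scenes into single-cell
bounding-box crops; removal of short-lifetime contaminants (mean lifetime
< 200 ps, e.g. red blood cells); removal of dim or cell-free frames by
thresholding image entropy and total intensity (cutoffs from Gaussian fits);
zero-padding of every crop to 82 x 82; six-fold augmentation (identity,
three rotations, two flips).  Per-donor cell counts are recorded after each
filter stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .synthetic import SyntheticCell

__all__ = [
    "SegmentedCell",
    "FilterThresholds",
    "ProcessedCell",
    "PAD_SIDE",
    "AUGMENTATION_TAGS",
    "segment_scene",
    "cells_from_synthetic",
    "lifetime_filter",
    "image_entropy",
    "entropy_intensity_filter",
    "pad_to_square",
    "augment",
    "run_preprocessing",
]

#: Common square size all crops are padded to (chosen in the original study
#: as the largest non-outlier bounding box).
PAD_SIDE = 82

AUGMENTATION_TAGS = ("original", "rot90", "rot180", "rot270",
                     "flip_h", "flip_v")

MIN_SEGMENT_AREA = 20  # px; connected components below this are discarded


@dataclass
class SegmentedCell:
    """A bounding-box crop of one segmented object."""

    image: np.ndarray            # 2D uint8 crop
    mask: np.ndarray             # 2D bool crop, same shape
    donor_id: str = ""
    label: str = ""
    mean_lifetime_ps: float | None = None
    cell_id: str = ""
    provenance: tuple = ()       # (scene id, object index)
    artifact_tag: str = "clean"

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("crop and mask shapes differ")
        if not self.mask.any():
            raise ValueError("segmented mask has no pixels")


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds.

    ``lifetime_min_ps``: cells with mean lifetime strictly below this are
    removed (default 200 ps).  Entropy/intensity cutoffs are either given
    explicitly or derived from Gaussian fits as mean - k_sigma * SD.
    """

    lifetime_min_ps: float = 200.0
    entropy_min_bits: float | None = None
    total_intensity_min: float | None = None
    k_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.lifetime_min_ps <= 0:
            raise ValueError("lifetime_min_ps must be positive")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")


@dataclass
class ProcessedCell:
    """An 82 x 82 zero-padded (possibly augmented) single-cell image."""

    image: np.ndarray            # side x side uint8
    donor_id: str
    label: str
    augmentation_tag: str = "original"
    source_id: str = ""
    mask: np.ndarray | None = None  # padded mask, kept for featurization

    def __post_init__(self) -> None:
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("processed image must be square")
        if self.augmentation_tag not in AUGMENTATION_TAGS:
            raise ValueError(f"unknown augmentation tag {self.augmentation_tag}")


def segment_scene(scene: np.ndarray, lifetime_map: np.ndarray | None = None,
                  min_area: int = MIN_SEGMENT_AREA, scene_id: str = "",
                  donor_id: str = "", label: str = "") -> list[SegmentedCell]:
    """Segment a grayscale scene into single-cell bounding-box crops.

    Global Otsu threshold, 8-connected components, minimum object area.
    When a lifetime map is given, each crop's mean lifetime is the map's
    mean over its mask.  Externally produced masks can bypass this via
    :func:`cells_from_synthetic`.
    """
    scene = np.asarray(scene)
    if scene.size == 0:
        raise ValueError("empty scene")
    if scene.max() == scene.min():
        return []  # featureless scene: no objects
    thr = threshold_otsu(scene)
    fg = scene > thr
    labels = cc_label(fg, connectivity=2)
    cells = []
    for idx in range(1, labels.max() + 1):
        mask = labels == idx
        if mask.sum() < min_area:
            continue
        ys, xs = np.nonzero(mask)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        mlt = None
        if lifetime_map is not None:
            mlt = float(np.asarray(lifetime_map)[mask].mean())
        cells.append(SegmentedCell(
            image=scene[sl].copy(), mask=mask[sl].copy(),
            mean_lifetime_ps=mlt, donor_id=donor_id, label=label,
            provenance=(scene_id, idx),
            cell_id=f"{scene_id}_obj{idx}" if scene_id else f"obj{idx}"))
    return cells


def cells_from_synthetic(cells: list[SyntheticCell]) -> list[SegmentedCell]:
    """Adopt ground-truth masks of synthetic cells as segmentations.

    Empty-mask frames (artifact_tag=empty) produce no segmented cell, the
    same outcome real segmentation would give on a cell-free frame.
    """
    out = []
    for i, cell in enumerate(cells):
        if not cell.mask.any():
            continue
        ys, xs = np.nonzero(cell.mask)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        out.append(SegmentedCell(
            image=cell.image[sl].copy(), mask=cell.mask[sl].copy(),
            mean_lifetime_ps=cell.mean_lifetime_ps,
            donor_id=cell.donor_id, label=cell.true_label,
            cell_id=cell.cell_id or f"{cell.donor_id}_{i:05d}",
            provenance=("synthetic", i), artifact_tag=cell.artifact_tag))
    return out


def lifetime_filter(cells: list[SegmentedCell],
                    thresholds: FilterThresholds = FilterThresholds()
                    ) -> list[SegmentedCell]:
    """Keep cells whose mean lifetime is >= the threshold.

    The boundary is strict on removal: exactly 200 ps is kept.  Cells with
    no lifetime information pass unchanged.  Negative lifetimes indicate a
    corrupt map and raise.
    """
    kept = []
    for cell in cells:
        if cell.mean_lifetime_ps is None or np.isnan(cell.mean_lifetime_ps):
            kept.append(cell)
            continue
        if cell.mean_lifetime_ps < 0:
            raise ValueError(
                f"negative mean lifetime for {cell.cell_id}: corrupt map")
        if cell.mean_lifetime_ps >= thresholds.lifetime_min_ps:
            kept.append(cell)
    return kept


def image_entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram.

    Bounded by [0, 8] for 8-bit images; 0 for a constant image, 8 when all
    256 values are equally frequent.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(image.astype(np.uint8).ravel(), minlength=256)
    p = counts[counts > 0] / image.size
    return float(-(p * np.log2(p)).sum())


def entropy_intensity_filter(
    cells: list[SegmentedCell],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[SegmentedCell], dict[str, float]]:
    """Remove dim / cell-free frames via entropy and total-intensity cutoffs.

    When explicit cutoffs are absent, each cutoff is fit as
    ``mean - k_sigma * SD`` of a Gaussian approximation to the per-cell
    statistic (requiring >= 10 cells).  A cell is kept iff it clears BOTH
    cutoffs.  Returns the kept cells and the cutoffs used.
    """
    ent = np.array([image_entropy(c.image) for c in cells])
    tot = np.array([float(c.image.sum()) for c in cells], dtype=float)

    e_cut = thresholds.entropy_min_bits
    i_cut = thresholds.total_intensity_min
    if e_cut is None or i_cut is None:
        if len(cells) < 10:
            raise ValueError(
                "need >= 10 cells to fit Gaussian cutoffs; pass explicit "
                "entropy_min_bits and total_intensity_min instead")
        if e_cut is None:
            sd = ent.std()
            if sd == 0:
                warnings.warn("zero entropy variance; cutoff set to the mean")
            e_cut = float(ent.mean() - thresholds.k_sigma * sd)
        if i_cut is None:
            sd = tot.std()
            if sd == 0:
                warnings.warn("zero intensity variance; cutoff set to the mean")
            i_cut = float(tot.mean() - thresholds.k_sigma * sd)

    keep = (ent >= e_cut) & (tot >= i_cut)
    kept = [c for c, k in zip(cells, keep) if k]
    return kept, {"entropy_min_bits": float(e_cut),
                  "total_intensity_min": float(i_cut)}


def pad_to_square(cell: SegmentedCell, side: int = PAD_SIDE
                  ) -> ProcessedCell | None:
    """Zero-pad a crop to ``side x side``, centered (odd remainder goes to
    the bottom/right).  Crops larger than ``side`` in either dimension are
    extremely large outliers and are discarded (returns None)."""
    h, w = cell.image.shape
    if h > side or w > side:
        return None
    top = (side - h) // 2
    left = (side - w) // 2
    img = np.zeros((side, side), dtype=np.uint8)
    img[top : top + h, left : left + w] = cell.image
    mask = np.zeros((side, side), dtype=bool)
    mask[top : top + h, left : left + w] = cell.mask
    return ProcessedCell(image=img, donor_id=cell.donor_id, label=cell.label,
                         augmentation_tag="original", source_id=cell.cell_id,
                         mask=mask)


_AUG_OPS = {
    "original": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
    "flip_h": lambda a: a[:, ::-1],
    "flip_v": lambda a: a[::-1, :],
}


def augment(cell: ProcessedCell) -> list[ProcessedCell]:
    """Return the six augmentation variants (identity + 90/180/270 degree
    rotations + horizontal and vertical flips) of a square cell image."""
    if cell.image.shape[0] != cell.image.shape[1]:
        raise ValueError("augmentation requires a square image")
    out = []
    for tag in AUGMENTATION_TAGS:
        op = _AUG_OPS[tag]
        out.append(ProcessedCell(
            image=np.ascontiguousarray(op(cell.image)),
            donor_id=cell.donor_id, label=cell.label,
            augmentation_tag=tag, source_id=cell.source_id,
            mask=(np.ascontiguousarray(op(cell.mask))
                  if cell.mask is not None else None)))
    return out


def run_preprocessing(
    cells: list[SegmentedCell],
    thresholds: FilterThresholds = FilterThresholds(),
    side: int = PAD_SIDE,
    do_augment: bool = True,
) -> tuple[list[ProcessedCell], pd.DataFrame]:
    """Run the cascade on segmented cells and report per-donor stage counts.

    Order is fixed: lifetime filter, then entropy/intensity filter, then
    padding (discarding oversize outliers), then augmentation.  The count
    report has one row per donor with the cell count after each stage,
    mirroring how the filtering stages are tabulated per donor.
    """
    def _counts(cs, stage):
        d: dict[str, int] = {}
        for c in cs:
            d[c.donor_id] = d.get(c.donor_id, 0) + 1
        return {"stage": stage, **d}

    stages = [_counts(cells, "original")]
    after_lt = lifetime_filter(cells, thresholds)
    stages.append(_counts(after_lt, "after_lifetime_filter"))
    after_ei, cutoffs = entropy_intensity_filter(after_lt, thresholds)
    stages.append(_counts(after_ei, "after_entropy_intensity_filter"))

    padded = []
    n_oversize = 0
    for cell in after_ei:
        p = pad_to_square(cell, side)
        if p is None:
            n_oversize += 1
        else:
            padded.append(p)
    stages.append(_counts(padded, "after_padding"))

    processed: list[ProcessedCell] = []
    if do_augment:
        for p in padded:
            processed.extend(augment(p))
    else:
        processed = padded
    stages.append(_counts(processed, "final"))

    report = pd.DataFrame(stages).fillna(0)
    report.attrs["cutoffs"] = cutoffs
    report.attrs["n_oversize_discarded"] = n_oversize
    return processed, report
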