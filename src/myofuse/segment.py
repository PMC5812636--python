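"""Myotube segmentation in the cytoplasm channel.

Pipeline: large-scale background subtraction (handles scaffold
autofluorescence) → threshold (Otsu or fixed) → morphological closing →
hole filling → 8-connected components → shape filtering.  Candidate regions
must be large and elongated; round mononucleated cell bodies are rejected by
the elongation cutoff, which stands in for the human judgement of what counts
as a "larger cell body".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk

from .core import FiberRegion, Image2D
from .errors import ConfigError, DimensionError


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters for fiber segmentation.

    background_radius_px
        Gaussian scale of the smooth background estimate subtracted before
        thresholding; large relative to fiber width.
    threshold_method
        ``"otsu"`` (default) or ``"fixed"`` (requires ``fixed_threshold``,
        applied to the background-subtracted image).
    min_area_px / min_elongation
        Shape gates: a candidate must cover at least ``min_area_px`` pixels
        and have major/minor axis ratio >= ``min_elongation``.
    closing_radius_px
        Radius of the morphological closing that smooths ragged edges.
    """

    background_radius_px: float = 50.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 200
    min_elongation: float = 3.0
    closing_radius_px: int = 2

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("threshold_method='fixed' requires fixed_threshold")
        if self.min_area_px < 1:
            raise ConfigError(f"min_area_px must be >= 1, got {self.min_area_px}")
        if self.min_elongation < 1:
            raise ConfigError(f"min_elongation must be >= 1, got {self.min_elongation}")


def segment_fibers(cyto_img: Image2D, cfg: SegmentationConfig | None = None) -> list[FiberRegion]:
    """Segment myotube candidate regions from the cytoplasm channel.

    Returns disjoint :class:`FiberRegion` objects labeled 1..n in raster
    order of each component's first pixel.  A blank image yields ``[]``.
    """
    cfg = cfg or SegmentationConfig()
    arr = np.asarray(cyto_img.pixels, dtype=np.float64)
    background = ndi.gaussian_filter(arr, cfg.background_radius_px)
    fg = arr - background
    if fg.max() <= fg.min():
        return []
    if cfg.threshold_method == "otsu":
        thr = threshold_otsu(fg)
    else:
        thr = float(cfg.fixed_threshold)
    mask = fg > thr
    if cfg.closing_radius_px > 0:
        mask = closing(mask, disk(cfg.closing_radius_px))
    mask = ndi.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)

    regions = []
    for props in regionprops(labels):
        if props.area < cfg.min_area_px:
            continue
        minor = float(props.axis_minor_length)
        major = float(props.axis_major_length)
        elong = major / minor if minor > 0 else np.inf
        if elong < cfg.min_elongation:
            continue
        # raster position of the component's first pixel, for stable labeling
        rows, cols = np.nonzero(labels == props.label)
        first = (int(rows[0]), int(cols[0]))
        regions.append((first, props.label))
    regions.sort()

    out = []
    for new_label, (_, old_label) in enumerate(regions, start=1):
        region_mask = labels == old_label
        out.append(FiberRegion.from_mask(new_label, region_mask))
    return out


def mask_iou(region: FiberRegion, truth_mask: np.ndarray) -> float:
    """Intersection-over-union between a segmented region and a truth mask."""
    truth = np.asarray(truth_mask, dtype=bool)
    if truth.shape != region.mask.shape:
        raise DimensionError(
            f"mask shapes differ: region {region.mask.shape} vs truth {truth.shape}"
        )
    inter = np.logical_and(region.mask, truth).sum()
    union = np.logical_or(region.mask, truth).sum()
    return float(inter / union) if union else 1.0
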