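"""Fusion metrics: nucleus-to-fiber assignment, fusion index, object contrast.

The fusion index is the percentage of all nuclei in a field that sit inside
fused fibers.  A fiber counts as fused only when it holds at least three
nuclei; a two-nucleus region is ambiguous (it may be a dividing cell) and
contributes nothing.  Assignment is by rounded-centroid containment: nuclei
are points, fibers are masks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core import (
    FUSED_NUCLEI_MIN,
    ContrastMeasurement,
    FiberRegion,
    FusionResult,
    Image2D,
    NucleusDetection,
    Scene,
)
from .detect import DetectionConfig, detect_nuclei
from .errors import StageError, UndefinedIndexError, ValidationError
from .segment import SegmentationConfig, segment_fibers


def assign_nuclei(
    detections: list[NucleusDetection], fibers: list[FiberRegion]
) -> list[FiberRegion]:
    """Assign each nucleus to the fiber whose mask contains its rounded centroid.

    Fiber masks are disjoint, so a nucleus lands in at most one fiber; nuclei
    outside every mask stay unassigned.  Returns new regions with
    ``nucleus_ids`` populated (input regions are not mutated).
    """
    out = [replace(f, nucleus_ids=[]) for f in fibers]
    if not out:
        return out
    shape = out[0].mask.shape
    label_img = np.zeros(shape, dtype=np.int32)
    for i, f in enumerate(out):
        label_img[f.mask] = i + 1
    h, w = shape
    for det in detections:
        xi, yi = int(np.rint(det.x)), int(np.rint(det.y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise ValidationError(
                f"nucleus {det.id} centroid ({det.x:.1f}, {det.y:.1f}) outside the image grid"
            )
        idx = label_img[yi, xi]
        if idx:
            out[idx - 1].nucleus_ids.append(det.id)
    return out


def fusion_index(
    detections: list[NucleusDetection],
    fibers_with_nuclei: list[FiberRegion],
    min_nuclei_per_fiber: int = FUSED_NUCLEI_MIN,
) -> FusionResult:
    """Compute the fusion index from detections and nucleus-annotated fibers.

    Raises :class:`UndefinedIndexError` when there are no nuclei at all — an
    empty field has no fusion index, and silently reporting 0% would dilute
    plate-level averages.
    """
    total = len(detections)
    if total == 0:
        raise UndefinedIndexError("no nuclei detected; fusion index is undefined")
    fused_fibers = [f for f in fibers_with_nuclei if len(f.nucleus_ids) >= min_nuclei_per_fiber]
    fused = sum(len(f.nucleus_ids) for f in fused_fibers)
    return FusionResult(
        total_nuclei=total,
        fused_nuclei=fused,
        fusion_index_pct=100.0 * fused / total,
        n_fused_fibers=len(fused_fibers),
        fiber_areas_px=tuple(f.area_px for f in fused_fibers),
    )


def _pixel_set_to_mask(px_set, shape) -> np.ndarray:
    arr = np.asarray(px_set)
    if arr.dtype == bool:
        if arr.shape != shape:
            raise ValidationError(f"pixel-set mask shape {arr.shape} != image shape {shape}")
        return arr
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pixel set must be a boolean mask or an (N, 2) array of (y, x)")
    mask = np.zeros(shape, dtype=bool)
    ys, xs = arr[:, 0].astype(int), arr[:, 1].astype(int)
    if (ys < 0).any() or (ys >= shape[0]).any() or (xs < 0).any() or (xs >= shape[1]).any():
        raise ValidationError("pixel set contains coordinates outside the image grid")
    mask[ys, xs] = True
    return mask


def object_contrast(img: Image2D, object_px, background_px) -> ContrastMeasurement:
    """Object contrast ``(S_j − bgd) / bgd``.

    ``S_j`` is the mean pixel value over the object region and ``bgd`` the
    mean over the background region.  Pixel sets may be boolean masks on the
    image grid or ``(N, 2)`` arrays of ``(y, x)`` indices, and must be
    disjoint and non-empty.
    """
    obj = _pixel_set_to_mask(object_px, img.shape)
    bgd_mask = _pixel_set_to_mask(background_px, img.shape)
    if not obj.any() or not bgd_mask.any():
        raise ValidationError("object and background pixel sets must be non-empty")
    if np.logical_and(obj, bgd_mask).any():
        raise ValidationError("object and background pixel sets overlap")
    arr = np.asarray(img.pixels, dtype=np.float64)
    s_j = float(arr[obj].mean())
    bgd = float(arr[bgd_mask].mean())
    if bgd == 0:
        raise ZeroDivisionError(
            "mean background intensity is zero; contrast (S_j - bgd)/bgd is undefined"
        )
    return ContrastMeasurement(
        contrast_j=(s_j - bgd) / bgd,
        s_j=s_j,
        bgd=bgd,
        n_object_px=int(obj.sum()),
        n_bgd_px=int(bgd_mask.sum()),
    )


def scene_metrics(
    scene: Scene,
    det_cfg: DetectionConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    min_nuclei_per_fiber: int = FUSED_NUCLEI_MIN,
) -> FusionResult:
    """Full per-scene pipeline: detect → segment → assign → fusion index."""
    try:
        detections = detect_nuclei(scene.nucleus, det_cfg)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("detect_nuclei", e) from e
    try:
        fibers = segment_fibers(scene.cytoplasm, seg_cfg)
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("segment_fibers", e) from e
    try:
        fibers = assign_nuclei(detections, fibers)
        return fusion_index(detections, fibers, min_nuclei_per_fiber)
    except UndefinedIndexError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("fusion_index", e) from e
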