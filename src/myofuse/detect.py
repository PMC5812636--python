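"""Nucleus detection in the nucleus channel.

Nuclei appear as compact bright spots of roughly known scale.  Detection is
scale-matched blob filtering — a (negated, scale-normalised)
Laplacian-of-Gaussian response — followed by thresholded local maxima and a
sub-pixel centroid refinement.  The threshold is relative to the filtered-image
maximum, so detections are invariant to overall gain, and peaks closer than
``min_separation_px`` are suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .core import Image2D, NucleusDetection
from .errors import ValidationError


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters for nucleus spot detection.

    sigma_px
        Expected nucleus scale (Gaussian sigma of the matched filter).
    rel_threshold
        Peak threshold as a fraction of the filtered-image maximum.
    min_separation_px
        Minimum distance between accepted peaks.
    border_margin_px
        Detections closer than this to the image edge are dropped
        (truncated spots bias centroids); defaults to ``2 * sigma_px``.
    """

    sigma_px: float = 3.0
    rel_threshold: float = 0.2
    min_separation_px: int = 5
    border_margin_px: int | None = None

    def __post_init__(self):
        if self.sigma_px <= 0:
            raise ValidationError(f"sigma_px must be > 0, got {self.sigma_px}")
        if not 0 < self.rel_threshold < 1:
            raise ValidationError(f"rel_threshold must be in (0, 1), got {self.rel_threshold}")
        if self.min_separation_px < 1:
            raise ValidationError(f"min_separation_px must be >= 1, got {self.min_separation_px}")

    @property
    def margin(self) -> int:
        if self.border_margin_px is not None:
            return int(self.border_margin_px)
        return int(math.ceil(2 * self.sigma_px))


def blob_response(pixels: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalised bright-blob response (−sigma² · LoG)."""
    arr = np.asarray(pixels, dtype=np.float64)
    return -(sigma_px**2) * ndi.gaussian_laplace(arr, sigma_px)


def detect_nuclei(nucleus_img: Image2D, cfg: DetectionConfig | None = None) -> list[NucleusDetection]:
    """Detect nuclei as sub-pixel centroids of blob-response maxima.

    Returns detections with ids assigned in raster order (row, then column)
    of the refined centroid.  A blank image yields an empty list.
    """
    cfg = cfg or DetectionConfig()
    resp = blob_response(nucleus_img.pixels, cfg.sigma_px)
    peak_max = resp.max()
    if peak_max <= 0:
        return []
    coords = peak_local_max(
        resp,
        min_distance=int(cfg.min_separation_px),
        threshold_abs=cfg.rel_threshold * peak_max,
        exclude_border=max(cfg.margin, 1),
    )
    h, w = resp.shape
    win = max(1, int(math.ceil(cfg.sigma_px)))
    detections = []
    for r, c in coords:
        y, x = _refine_centroid(resp, int(r), int(c), win)
        if not (cfg.margin <= x < w - cfg.margin and cfg.margin <= y < h - cfg.margin):
            continue
        yi, xi = int(round(y)), int(round(x))
        detections.append((y, x, float(nucleus_img.pixels[yi, xi])))
    detections.sort(key=lambda t: (t[0], t[1]))
    return [
        NucleusDetection(x=x, y=y, intensity=inten, id=i)
        for i, (y, x, inten) in enumerate(detections)
    ]


def _refine_centroid(resp: np.ndarray, r: int, c: int, win: int) -> tuple[float, float]:
    """Center of mass of the positive response in a (2·win+1)² window."""
    h, w = resp.shape
    r0, r1 = max(0, r - win), min(h, r + win + 1)
    c0, c1 = max(0, c - win), min(w, c + win + 1)
    patch = np.clip(resp[r0:r1, c0:c1], 0, None)
    total = patch.sum()
    if total <= 0:
        return float(r), float(c)
    ys, xs = np.mgrid[r0:r1, c0:c1]
    return float((ys * patch).sum() / total), float((xs * patch).sum() / total)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detections against ground-truth nuclei."""

    true_pos: int
    false_pos: int
    false_neg: int
    recall: float
    precision: float
    precision_defined: bool = True


def match_detections(detections, truth_nuclei, max_dist_px: float) -> MatchResult:
    """One-to-one greedy nearest-neighbour matching under a distance cap.

    Pairs are accepted in order of increasing distance; ties are broken
    towards the lower-index truth, then the lower-index detection.  With no
    detections at all, precision is reported as 1.0 by convention with
    ``precision_defined=False``.
    """
    if max_dist_px <= 0:
        raise ValidationError(f"max_dist_px must be > 0, got {max_dist_px}")
    det_xy = np.array([[d.x, d.y] for d in detections], dtype=float).reshape(-1, 2)
    tru_xy = np.array([[t.x, t.y] for t in truth_nuclei], dtype=float).reshape(-1, 2)
    pairs = []
    for ti in range(len(tru_xy)):
        d = np.hypot(det_xy[:, 0] - tru_xy[ti, 0], det_xy[:, 1] - tru_xy[ti, 1])
        for di in np.nonzero(d <= max_dist_px)[0]:
            pairs.append((float(d[di]), ti, int(di)))
    pairs.sort()
    used_t, used_d = set(), set()
    tp = 0
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        tp += 1
    fp = len(det_xy) - tp
    fn = len(tru_xy) - tp
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    if tp + fp:
        precision, defined = tp / (tp + fp), True
    else:
        precision, defined = 1.0, False
    return MatchResult(tp, fp, fn, recall, precision, defined)
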