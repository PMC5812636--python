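"""Domain types shared by all modules.

The package analyses paired single-plane fluorescence images of cultured
myoblasts: a *cytoplasm* channel in which elongated multinucleated myotubes
(fibers) are visible, and a *nucleus* channel containing one bright spot per
nucleus.  The quantities of interest are the nuclei count (a proxy for cell
growth) and the fusion index — the percentage of all nuclei that sit inside
fused fibers, where a fiber counts as fused only when it holds at least three
nuclei (two co-located nuclei may simply be a dividing cell).

Conventions: coordinates are 0-based with ``x`` = column and ``y`` = row;
masks are pixel-aligned boolean arrays on the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ValidationError

CHANNELS = ("cytoplasm", "nucleus")
BIT_DEPTHS = (8, 16)

#: minimum nuclei for a multinucleated region to count as fused
FUSED_NUCLEI_MIN = 3


@dataclass(frozen=True)
class Image2D:
    """Single-plane grayscale fluorescence image.

    Parameters
    ----------
    pixels
        2-D non-negative intensity array.
    bit_depth
        8 or 16; intensities must fit in ``[0, 2**bit_depth - 1]``.
    channel
        ``"cytoplasm"`` or ``"nucleus"``.
    pixel_size_um
        Physical pixel size in micrometers (metadata only).
    """

    pixels: np.ndarray
    bit_depth: int
    channel: str
    pixel_size_um: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise DimensionError(f"expected a 2-D image, got ndim={px.ndim}")
        if min(px.shape) < 16:
            raise ValidationError(f"image dimensions must be >= 16, got {px.shape}")
        if self.bit_depth not in BIT_DEPTHS:
            raise ValidationError(f"bit_depth must be one of {BIT_DEPTHS}, got {self.bit_depth}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValidationError(
                f"intensities outside [0, {2**self.bit_depth - 1}] for bit_depth={self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Scene:
    """One field of view: paired cytoplasm/nucleus images plus plate metadata."""

    cytoplasm: Image2D
    nucleus: Image2D
    well_id: str
    day: int
    condition: str = ""
    field_index: int = 0

    def __post_init__(self):
        if self.cytoplasm.shape != self.nucleus.shape:
            raise DimensionError(
                f"channel shapes differ: cytoplasm {self.cytoplasm.shape} "
                f"vs nucleus {self.nucleus.shape}"
            )
        if self.cytoplasm.channel != "cytoplasm" or self.nucleus.channel != "nucleus":
            raise ValidationError("Scene channels must be tagged cytoplasm/nucleus respectively")
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if self.field_index < 0:
            raise ValidationError(f"field_index must be >= 0, got {self.field_index}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cytoplasm.shape


@dataclass(frozen=True)
class NucleusDetection:
    """Sub-pixel centroid of one detected nucleus (x = column, y = row)."""

    x: float
    y: float
    intensity: float
    id: int


@dataclass
class FiberRegion:
    """A labeled connected region classified as a myotube candidate."""

    label: int
    mask: np.ndarray
    area_px: int
    major_axis_px: float
    minor_axis_px: float
    elongation: float
    nucleus_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.label < 1:
            raise ValidationError(f"region label must be >= 1, got {self.label}")
        if self.area_px != int(self.mask.sum()):
            raise ValidationError("area_px does not equal the mask pixel count")
        if self.elongation < 1:
            raise ValidationError(f"elongation must be >= 1, got {self.elongation}")

    @classmethod
    def from_mask(cls, label: int, mask: np.ndarray) -> "FiberRegion":
        """Build a region from a boolean mask, computing moment-based shape
        descriptors (best-fit-ellipse axis lengths)."""
        from skimage.measure import regionprops

        mask = np.asarray(mask, dtype=bool)
        props = regionprops(mask.astype(np.uint8))[0]
        major = float(props.axis_major_length)
        minor = float(props.axis_minor_length)
        elong = major / minor if minor > 0 else np.inf
        return cls(
            label=label,
            mask=mask,
            area_px=int(mask.sum()),
            major_axis_px=major,
            minor_axis_px=minor,
            elongation=max(elong, 1.0),
        )


@dataclass(frozen=True)
class FusionResult:
    """Per-scene fusion metrics.

    ``fused_nuclei`` counts nuclei in fibers holding >= 3 nuclei;
    ``fiber_areas_px`` lists the pixel areas of those fused fibers.
    """

    total_nuclei: int
    fused_nuclei: int
    fusion_index_pct: float
    n_fused_fibers: int
    fiber_areas_px: tuple[int, ...] = ()

    def __post_init__(self):
        if self.total_nuclei < 0 or self.fused_nuclei < 0:
            raise ValidationError("nucleus counts must be non-negative")
        if self.fused_nuclei > self.total_nuclei:
            raise ValidationError("fused_nuclei cannot exceed total_nuclei")
        if self.total_nuclei > 0:
            expected = 100.0 * self.fused_nuclei / self.total_nuclei
            if abs(self.fusion_index_pct - expected) > 1e-9:
                raise ValidationError("fusion_index_pct inconsistent with counts")
        if self.n_fused_fibers != len(self.fiber_areas_px):
            raise ValidationError("n_fused_fibers must match len(fiber_areas_px)")

    @property
    def mean_fiber_area_px(self) -> float:
        if not self.fiber_areas_px:
            return float("nan")
        return float(np.mean(self.fiber_areas_px))


@dataclass(frozen=True)
class ContrastMeasurement:
    """Object contrast: ``(mean object − mean background) / mean background``."""

    contrast_j: float
    s_j: float
    bgd: float
    n_object_px: int
    n_bgd_px: int

    def __post_init__(self):
        if self.n_object_px < 1 or self.n_bgd_px < 1:
            raise ValidationError("object and background pixel sets must be non-empty")
        if self.bgd <= 0:
            raise ValidationError("mean background must be positive")


_PRESET_SCHEDULES = {
    "ND": frozenset(),
    "continuous": frozenset(range(3, 11)),
    "early": frozenset({3, 4, 5}),
    "late": frozenset({7, 8, 9}),
}


@dataclass(frozen=True)
class ExposureSchedule:
    """Drug exposure window during a differentiation time course.

    Presets mirror the standard screening schedules: no drug (ND),
    continuous exposure days 3–10, early exposure days 3–5 and late
    exposure days 7–9, with differentiation media introduced at day 3.
    """

    name: str
    drug_days: frozenset[int]
    differentiation_start_day: int = 3

    def __post_init__(self):
        object.__setattr__(self, "drug_days", frozenset(self.drug_days))
        preset = _PRESET_SCHEDULES.get(self.name)
        if preset is not None and self.drug_days != preset:
            raise ValidationError(
                f"schedule {self.name!r} must have drug_days {sorted(preset)}, "
                f"got {sorted(self.drug_days)}"
            )
        if any(d < 0 for d in self.drug_days):
            raise ValidationError("drug_days must be non-negative")

    @classmethod
    def preset(cls, name: str, differentiation_start_day: int = 3) -> "ExposureSchedule":
        if name not in _PRESET_SCHEDULES:
            raise ValidationError(
                f"unknown schedule preset {name!r}; choose from {sorted(_PRESET_SCHEDULES)}"
            )
        return cls(name, _PRESET_SCHEDULES[name], differentiation_start_day)

    def effect_on(self, day: int, drug_effect: float) -> float:
        """Multiplier applied to the fusion rate on ``day``."""
        return drug_effect if day in self.drug_days else 1.0


@dataclass(frozen=True)
class TrueNucleus:
    """Ground-truth nucleus: centroid plus fiber membership (or ``None``)."""

    x: float
    y: float
    fiber_id: int | None


@dataclass
class GroundTruth:
    """Simulator-emitted truth for one scene: nucleus centroids with fiber
    membership and the labeled fiber mask image."""

    nuclei: list[TrueNucleus]
    fiber_masks: np.ndarray
    true_fusion_index_pct: float
    true_nuclei_count: int

    def __post_init__(self):
        self.fiber_masks = np.asarray(self.fiber_masks)
        labels = set(np.unique(self.fiber_masks)) - {0}
        for nuc in self.nuclei:
            if nuc.fiber_id is not None and nuc.fiber_id not in labels:
                raise ValidationError(f"nucleus references missing fiber label {nuc.fiber_id}")
        if self.true_nuclei_count != len(self.nuclei):
            raise ValidationError("true_nuclei_count inconsistent with nuclei list")
        expected = fusion_index_from_memberships([n.fiber_id for n in self.nuclei])
        if abs(expected - self.true_fusion_index_pct) > 1e-9:
            raise ValidationError("true_fusion_index_pct inconsistent with memberships")

    @property
    def fused_fiber_labels(self) -> list[int]:
        """Labels of ground-truth fibers holding >= 3 nuclei."""
        counts: dict[int, int] = {}
        for nuc in self.nuclei:
            if nuc.fiber_id is not None:
                counts[nuc.fiber_id] = counts.get(nuc.fiber_id, 0) + 1
        return sorted(k for k, v in counts.items() if v >= FUSED_NUCLEI_MIN)


def fusion_index_from_memberships(memberships: list[int | None]) -> float:
    """Fusion index (%) from per-nucleus fiber memberships via the >= 3 rule.

    ``memberships[i]`` is the fiber id of nucleus ``i`` or ``None``.  Nuclei in
    fibers with fewer than three members contribute nothing (they may be
    dividing cells rather than a fused myotube).
    """
    total = len(memberships)
    if total == 0:
        return 0.0
    counts: dict[int, int] = {}
    for m in memberships:
        if m is not None:
            counts[m] = counts.get(m, 0) + 1
    fused = sum(v for v in counts.values() if v >= FUSED_NUCLEI_MIN)
    return 100.0 * fused / total
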