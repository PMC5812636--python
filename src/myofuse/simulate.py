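"""Synthetic double-labeled myoblast scene generator with exact ground truth.

The simulator emulates differentiating C2C12-style cultures imaged live in two
fluorescence channels: round mononucleated cell bodies and elongated
multinucleated myotubes in the cytoplasm channel, one compact bright spot per
nucleus in the nucleus channel, on an autofluorescent background (bright for
scaffold scenarios) with Poisson shot noise plus Gaussian read noise.

Population dynamics over a differentiation time course:

* nuclei count grows geometrically ``n(t) = n0 * growth_rate**t`` until it
  reaches ``plateau_nuclei`` (confluence), and is unaffected by drug;
* the fused fraction ``f(t)`` starts at 0 when differentiation media is
  introduced and accumulates logistically,
  ``df/dt = fusion_rate * effect(t) * (f_max - f)``, integrated exactly over
  unit-day steps, where ``effect(t)`` is ``drug_effect`` on scheduled drug
  days and 1 otherwise.  ``drug_effect = 0`` therefore freezes fusion for the
  exposure window, mimicking a fully inhibitory drug such as continuous TNFα.

Fibers are rendered as randomly oriented capsules with their nuclei spaced
along the major axis; fiber length grows with the number of member nuclei.
A configurable low rate of two-nucleus capsules exercises the ambiguous
"two nuclei: fused or dividing?" case; they are never counted as fused.
Object placement is rejection-sampled with a clearance margin so that
ground-truth masks stay disjoint.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import (
    ExposureSchedule,
    GroundTruth,
    Image2D,
    Scene,
    TrueNucleus,
    fusion_index_from_memberships,
)
from .errors import SimulationError, ValidationError
from . import io as mio


def _default_gains() -> dict:
    # cGFP+nmCherry images with the higher cytoplasm and nucleus
    # signal-to-background, matching the observed contrast ordering of the
    # two label combinations on culture plates.
    return {
        "cGFP+nmCherry": {"cytoplasm": 120.0, "nucleus": 320.0},
        "cmCherry+nGFP": {"cytoplasm": 60.0, "nucleus": 160.0},
    }


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic culture; defaults describe a plastic-plate
    culture at standard imaging settings.

    Geometry is in pixels, intensities in camera counts (16-bit range).
    ``fusion_rate`` is per day; ``f_max`` is the asymptotic fused fraction;
    ``drug_effect`` multiplies the fusion rate on scheduled drug days.
    """

    width: int = 384
    height: int = 384
    n_nuclei_day0: int = 30
    growth_rate: float = 1.4
    plateau_nuclei: int = 90
    fusion_rate: float = 0.5
    f_max: float = 0.6
    drug_effect: float = 1.0
    label_combo: str = "cGFP+nmCherry"
    channel_gains: dict = field(default_factory=_default_gains)
    autofluorescence_level: float = 20.0
    read_noise_sigma: float = 3.0
    nucleus_radius_px: float = 3.0
    fiber_width_px: float = 10.0
    cell_radius_px: float = 7.0
    nucleus_spacing_px: float = 16.0
    binucleate_rate: float = 0.05
    biological_cv: float = 0.05
    border_margin_px: int = 20
    clearance_px: float = 6.0
    max_placement_retries: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValidationError("image dimensions must be >= 64")
        if not 0 <= self.f_max <= 1:
            raise ValidationError(f"f_max must be in [0, 1], got {self.f_max}")
        if not 0 <= self.drug_effect <= 1:
            raise ValidationError(f"drug_effect must be in [0, 1], got {self.drug_effect}")
        if self.fusion_rate < 0 or self.growth_rate <= 0:
            raise ValidationError("fusion_rate must be >= 0 and growth_rate > 0")
        if self.label_combo not in self.channel_gains:
            raise ValidationError(f"label_combo {self.label_combo!r} missing from channel_gains")
        gains = self.channel_gains[self.label_combo]
        if gains["cytoplasm"] <= 0 or gains["nucleus"] <= 0:
            raise ValidationError("channel gains must be > 0")
        if self.autofluorescence_level <= 0:
            raise ValidationError("autofluorescence_level must be > 0")
        if not 0 <= self.binucleate_rate <= 1:
            raise ValidationError(f"binucleate_rate must be in [0, 1], got {self.binucleate_rate}")
        if self.biological_cv < 0:
            raise ValidationError(f"biological_cv must be >= 0, got {self.biological_cv}")
        if self.n_nuclei_day0 < 0 or self.plateau_nuclei < 1:
            raise ValidationError("nucleus counts must be positive")


def nuclei_count_at(params: SimulationParams, day: int) -> int:
    """Geometric growth capped at the confluence plateau."""
    if day < 0:
        raise ValidationError(f"day must be >= 0, got {day}")
    return int(min(round(params.n_nuclei_day0 * params.growth_rate**day), params.plateau_nuclei))


def fused_fraction_at(
    params: SimulationParams, schedule: ExposureSchedule, day: int
) -> float:
    """Integrate the logistic fused-fraction ODE over unit-day steps.

    Each day ``t`` from the differentiation start contributes an exact
    exponential step ``f <- f_max - (f_max - f) * exp(-rate * effect(t))``.
    The sequence is non-decreasing, and a fully inhibitory drug
    (``drug_effect = 0``) leaves ``f`` unchanged across its exposure window.
    """
    if day < 0:
        raise ValidationError(f"day must be >= 0, got {day}")
    f = 0.0
    for t in range(schedule.differentiation_start_day, day):
        eff = schedule.effect_on(t, params.drug_effect)
        f = params.f_max - (params.f_max - f) * np.exp(-params.fusion_rate * eff)
    return float(f)


def _fiber_sizes(rng: np.random.Generator, n_fused_target: int) -> list[int]:
    """Partition the fused-nucleus budget into fibers of >= 3 nuclei.

    Up to 2 leftover nuclei that cannot form a fiber return to the solitary
    pool, so the realized fused count deviates from the target by at most 2.
    """
    sizes = []
    rem = n_fused_target
    while rem >= 3:
        s = min(int(rng.integers(3, 7)), rem)
        if 0 < rem - s < 3:
            s = rem if rem <= 8 else rem - 3
        sizes.append(s)
        rem -= s
    return sizes


def _capsule_mask(h, w, p0, p1, half_width) -> np.ndarray:
    """Boolean mask of pixels within ``half_width`` of segment p0–p1."""
    x0, y0 = p0
    x1, y1 = p1
    lo_x = int(np.floor(min(x0, x1) - half_width - 1))
    hi_x = int(np.ceil(max(x0, x1) + half_width + 1))
    lo_y = int(np.floor(min(y0, y1) - half_width - 1))
    hi_y = int(np.ceil(max(y0, y1) + half_width + 1))
    mask = np.zeros((h, w), dtype=bool)
    lo_x, hi_x = max(lo_x, 0), min(hi_x, w - 1)
    lo_y, hi_y = max(lo_y, 0), min(hi_y, h - 1)
    if lo_x > hi_x or lo_y > hi_y:
        return mask
    ys, xs = np.mgrid[lo_y : hi_y + 1, lo_x : hi_x + 1]
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        dist = np.hypot(xs - x0, ys - y0)
    else:
        t = np.clip(((xs - x0) * dx + (ys - y0) * dy) / seg2, 0, 1)
        dist = np.hypot(xs - (x0 + t * dx), ys - (y0 + t * dy))
    mask[lo_y : hi_y + 1, lo_x : hi_x + 1] = dist <= half_width
    return mask


def _inside_margin(mask: np.ndarray, margin: int) -> bool:
    if margin <= 0:
        return True
    return not (
        mask[:margin, :].any()
        or mask[-margin:, :].any()
        or mask[:, :margin].any()
        or mask[:, -margin:].any()
    )


@dataclass
class _ScenePopulation:
    nuclei: list[TrueNucleus]
    fiber_labels: np.ndarray
    cell_disks: list[tuple[float, float]]


def _place_population(
    params: SimulationParams, rng: np.random.Generator, n_nuclei: int, fused_fraction: float
) -> _ScenePopulation:
    h, w = params.height, params.width
    margin = params.border_margin_px
    half_w = params.fiber_width_px / 2.0
    spacing = params.nucleus_spacing_px

    target = int(round(fused_fraction * n_nuclei))
    sizes = _fiber_sizes(rng, target)
    unfused = n_nuclei - sum(sizes)
    n_pairs = int(np.floor(params.binucleate_rate * unfused / 2))
    n_solitary = unfused - 2 * n_pairs

    occupancy = np.zeros((h, w), dtype=bool)
    fiber_labels = np.zeros((h, w), dtype=np.int32)
    nuclei: list[TrueNucleus] = []
    cell_disks: list[tuple[float, float]] = []
    next_label = 1

    def place_capsule(k: int) -> None:
        nonlocal next_label, occupancy
        seg_len = (k - 1) * spacing
        for _ in range(params.max_placement_retries):
            theta = rng.uniform(0, np.pi)
            dxu, dyu = np.cos(theta), np.sin(theta)
            pad = margin + half_w + 2
            cx = rng.uniform(pad, w - pad)
            cy = rng.uniform(pad, h - pad)
            p0 = (cx - dxu * seg_len / 2, cy - dyu * seg_len / 2)
            p1 = (cx + dxu * seg_len / 2, cy + dyu * seg_len / 2)
            mask = _capsule_mask(h, w, p0, p1, half_w)
            if not _inside_margin(mask, margin) or (mask & occupancy).any():
                continue
            grown = _capsule_mask(h, w, p0, p1, half_w + params.clearance_px)
            occupancy |= grown
            fiber_labels[mask] = next_label
            for i in range(k):
                jx = rng.uniform(-1, 1)
                jy = rng.uniform(-1, 1)
                nx = p0[0] + dxu * spacing * i + jx
                ny = p0[1] + dyu * spacing * i + jy
                nuclei.append(TrueNucleus(x=float(nx), y=float(ny), fiber_id=next_label))
            next_label += 1
            return
        raise SimulationError(
            f"could not place a {k}-nucleus fiber after "
            f"{params.max_placement_retries} retries; scene too crowded"
        )

    def place_cell() -> None:
        nonlocal occupancy
        r = params.cell_radius_px
        for _ in range(params.max_placement_retries):
            pad = margin + r + 1
            cx = rng.uniform(pad, w - pad)
            cy = rng.uniform(pad, h - pad)
            mask = _capsule_mask(h, w, (cx, cy), (cx, cy), r)
            if (mask & occupancy).any():
                continue
            occupancy |= _capsule_mask(h, w, (cx, cy), (cx, cy), r + params.clearance_px)
            jx, jy = rng.uniform(-1, 1), rng.uniform(-1, 1)
            nuclei.append(TrueNucleus(x=float(cx + jx), y=float(cy + jy), fiber_id=None))
            cell_disks.append((cx, cy))
            return
        raise SimulationError(
            f"could not place a mononucleated cell after "
            f"{params.max_placement_retries} retries; scene too crowded"
        )

    # big objects first: fibers, then two-nucleus capsules, then single cells
    for k in sorted(sizes, reverse=True):
        place_capsule(k)
    for _ in range(n_pairs):
        place_capsule(2)
    for _ in range(n_solitary):
        place_cell()

    return _ScenePopulation(nuclei=nuclei, fiber_labels=fiber_labels, cell_disks=cell_disks)


def _render(
    params: SimulationParams, rng: np.random.Generator, pop: _ScenePopulation
) -> tuple[np.ndarray, np.ndarray]:
    from scipy import ndimage as ndi

    h, w = params.height, params.width
    gains = params.channel_gains[params.label_combo]
    cyto = np.zeros((h, w), dtype=np.float64)
    cyto[pop.fiber_labels > 0] = gains["cytoplasm"]
    for cx, cy in pop.cell_disks:
        disk = _capsule_mask(h, w, (cx, cy), (cx, cy), params.cell_radius_px)
        cyto[disk] = gains["cytoplasm"]
    cyto = ndi.gaussian_filter(cyto, 1.0)

    nuc = np.zeros((h, w), dtype=np.float64)
    sig = params.nucleus_radius_px
    rad = int(np.ceil(4 * sig))
    for n in pop.nuclei:
        x0, y0 = n.x, n.y
        lo_x, hi_x = max(int(x0) - rad, 0), min(int(x0) + rad + 1, w)
        lo_y, hi_y = max(int(y0) - rad, 0), min(int(y0) + rad + 1, h)
        ys, xs = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        nuc[lo_y:hi_y, lo_x:hi_x] += gains["nucleus"] * np.exp(
            -((xs - x0) ** 2 + (ys - y0) ** 2) / (2 * sig**2)
        )

    out = []
    for clean in (cyto, nuc):
        lam = clean + params.autofluorescence_level
        noisy = rng.poisson(lam).astype(np.float64)
        noisy += rng.normal(0.0, params.read_noise_sigma, size=lam.shape)
        out.append(np.clip(np.rint(noisy), 0, 2**16 - 1).astype(np.uint16))
    return out[0], out[1]


def render_scene(
    params: SimulationParams,
    n_nuclei: int,
    fused_fraction: float,
    rng: np.random.Generator,
    well_id: str = "W0",
    day: int = 0,
    condition: str = "",
    field_index: int = 0,
) -> tuple[Scene, GroundTruth]:
    """Render one scene for an explicit population state (count + fused
    fraction); the time-course logic lives in the ``simulate_*`` wrappers."""
    if not 0 <= fused_fraction <= 1:
        raise ValidationError(f"fused_fraction must be in [0, 1], got {fused_fraction}")
    pop = _place_population(params, rng, n_nuclei, fused_fraction)
    cyto_px, nuc_px = _render(params, rng, pop)
    scene = Scene(
        cytoplasm=Image2D(cyto_px, 16, "cytoplasm"),
        nucleus=Image2D(nuc_px, 16, "nucleus"),
        well_id=well_id,
        day=day,
        condition=condition,
        field_index=field_index,
    )
    truth = GroundTruth(
        nuclei=pop.nuclei,
        fiber_masks=pop.fiber_labels,
        true_fusion_index_pct=fusion_index_from_memberships(
            [n.fiber_id for n in pop.nuclei]
        ),
        true_nuclei_count=len(pop.nuclei),
    )
    return scene, truth


def scene_rng(master_seed: int, condition: str, well: int, day: int, field: int) -> np.random.Generator:
    """Deterministic per-(condition, well, day, field) random stream.

    Streams are derived by seeding with a named key, so adding wells or
    conditions never perturbs existing scenes.
    """
    key = zlib.crc32(condition.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key, well, day, field])
    return np.random.default_rng(ss)


def _jitter_state(
    params: SimulationParams, rng: np.random.Generator, n: int, f: float
) -> tuple[int, float]:
    """Well-to-well biological variability: multiplicative Gaussian jitter on
    the nuclei count and fused fraction (CV = ``biological_cv``)."""
    if params.biological_cv > 0:
        n = max(0, int(round(n * (1 + params.biological_cv * rng.standard_normal()))))
        f = float(np.clip(f * (1 + params.biological_cv * rng.standard_normal()), 0.0, 1.0))
    return n, f


def simulate_scene(
    params: SimulationParams,
    day: int,
    schedule: ExposureSchedule | None = None,
    well_id: str = "W0",
    condition: str = "",
    field_index: int = 0,
) -> tuple[Scene, GroundTruth]:
    """Simulate one field of view at ``day`` of a differentiation course."""
    schedule = schedule or ExposureSchedule.preset("ND")
    n = nuclei_count_at(params, day)
    f = fused_fraction_at(params, schedule, day)
    rng = scene_rng(params.seed, condition or schedule.name, 0, day, field_index)
    n, f = _jitter_state(params, rng, n, f)
    return render_scene(
        params, n, f, rng, well_id=well_id, day=day, condition=condition, field_index=field_index
    )


def simulate_timecourse(
    params: SimulationParams,
    schedule: ExposureSchedule,
    days: list[int],
    well_id: str = "W0",
    condition: str = "",
) -> list[tuple[Scene, GroundTruth]]:
    """Simulate one well across a differentiation time course."""
    if list(days) != sorted(days):
        raise ValidationError(f"days must be sorted ascending, got {list(days)}")
    return [
        simulate_scene(
            params, day, schedule, well_id=well_id, condition=condition or schedule.name
        )
        for day in days
    ]


@dataclass
class PlateRecord:
    condition: str
    well_id: str
    day: int
    field_index: int
    scene: Scene
    ground_truth: GroundTruth
    path: str | None = None


def simulate_plate(
    conditions: list[tuple[str, SimulationParams, ExposureSchedule]],
    n_wells: int,
    n_fields: int,
    days: list[int],
    seed: int,
    out_dir=None,
) -> tuple[list[PlateRecord], dict]:
    """Simulate a multi-condition plate experiment.

    ``conditions`` is a list of ``(name, params, schedule)``; per-scene random
    streams are derived from the master ``seed``.  With ``out_dir`` given,
    scene bundles and a ``manifest.json`` are written there.  Returns
    ``(records, manifest)``.
    """
    names = [c[0] for c in conditions]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate condition names in {names}")
    if n_wells < 1 or n_fields < 1:
        raise ValidationError("n_wells and n_fields must be >= 1")
    if list(days) != sorted(days):
        raise ValidationError(f"days must be sorted ascending, got {list(days)}")

    records = []
    for name, params, schedule in conditions:
        for well in range(n_wells):
            well_id = f"{name}-w{well}"
            for day in days:
                n = nuclei_count_at(params, day)
                f = fused_fraction_at(params, schedule, day)
                for fi in range(n_fields):
                    rng = scene_rng(seed, name, well, day, fi)
                    n_w, f_w = _jitter_state(params, rng, n, f)
                    scene, truth = render_scene(
                        params,
                        n_w,
                        f_w,
                        rng,
                        well_id=well_id,
                        day=day,
                        condition=name,
                        field_index=fi,
                    )
                    records.append(PlateRecord(name, well_id, day, fi, scene, truth))

    manifest = {
        "seed": int(seed),
        "conditions": names,
        "n_wells": n_wells,
        "n_fields": n_fields,
        "days": list(days),
        "scenes": [],
    }
    for rec in records:
        entry = {
            "condition": rec.condition,
            "well_id": rec.well_id,
            "day": rec.day,
            "field_index": rec.field_index,
            "true_fusion_index_pct": rec.ground_truth.true_fusion_index_pct,
            "true_nuclei_count": rec.ground_truth.true_nuclei_count,
        }
        if out_dir is not None:
            rel = f"{rec.well_id}_d{rec.day}_f{rec.field_index}"
            mio.write_scene_bundle(rec.scene, Path(out_dir) / rel, rec.ground_truth)
            rec.path = rel
            entry["path"] = rel
        manifest["scenes"].append(entry)
    if out_dir is not None:
        import json

        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return records, manifest


def scaffold_params(params: SimulationParams | None = None) -> SimulationParams:
    """Variant of ``params`` emulating an autofluorescent collagen scaffold
    background (brighter, noisier baseline)."""
    base = params or SimulationParams()
    return replace(base, autofluorescence_level=3 * base.autofluorescence_level)
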