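"""Readers and writers: TIFF images, scene bundles, and result tables.

A *scene bundle* is a directory holding ``cytoplasm.tif`` and ``nucleus.tif``
(single-plane grayscale TIFF), a ``scene.json`` metadata sidecar and, for
simulated scenes, ``fiber_labels.tif`` with the ground-truth label image.
Everything is inspectable with standard viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BIT_DEPTHS, GroundTruth, Image2D, Scene, TrueNucleus
from .errors import DimensionError, EmptyResultError, FormatError

_DTYPES = {8: np.uint8, 16: np.uint16}

RESULT_COLUMNS = [
    "well_id",
    "condition",
    "day",
    "field_index",
    "total_nuclei",
    "fused_nuclei",
    "fusion_index_pct",
    "n_fused_fibers",
    "mean_fiber_area_px",
]


def read_image(path, channel: str, pixel_size_um: float = 1.0) -> Image2D:
    """Read one single-plane grayscale TIFF as an :class:`Image2D`.

    Multi-plane, RGB and unknown-bit-depth files are rejected rather than
    coerced: silent rescaling would corrupt contrast measurements.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-plane grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16 "
            f"(bit depths {BIT_DEPTHS})"
        )
    return Image2D(pixels=arr, bit_depth=depth, channel=channel, pixel_size_um=pixel_size_um)


def write_image(img: Image2D, path) -> None:
    tifffile.imwrite(Path(path), img.pixels.astype(_DTYPES[img.bit_depth]))


def read_scene(
    cyto_path,
    nuc_path,
    well_id: str,
    day: int,
    condition: str = "",
    field_index: int = 0,
    pixel_size_um: float = 1.0,
) -> Scene:
    """Read a paired cytoplasm/nucleus TIFF into a :class:`Scene`."""
    cyto = read_image(cyto_path, "cytoplasm", pixel_size_um)
    nuc = read_image(nuc_path, "nucleus", pixel_size_um)
    if cyto.shape != nuc.shape:
        raise DimensionError(
            f"channel shapes differ: {cyto_path} {cyto.shape} vs {nuc_path} {nuc.shape}"
        )
    return Scene(
        cytoplasm=cyto,
        nucleus=nuc,
        well_id=well_id,
        day=day,
        condition=condition,
        field_index=field_index,
    )


def write_scene_bundle(scene: Scene, bundle_dir, ground_truth: GroundTruth | None = None) -> Path:
    """Write a scene (and optional ground truth) as an inspectable directory."""
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    write_image(scene.cytoplasm, bundle_dir / "cytoplasm.tif")
    write_image(scene.nucleus, bundle_dir / "nucleus.tif")
    meta = {
        "well_id": scene.well_id,
        "day": scene.day,
        "condition": scene.condition,
        "field_index": scene.field_index,
        "bit_depth": scene.cytoplasm.bit_depth,
        "pixel_size_um": scene.cytoplasm.pixel_size_um,
    }
    if ground_truth is not None:
        meta["ground_truth"] = {
            "nuclei": [[n.x, n.y, n.fiber_id] for n in ground_truth.nuclei],
            "true_fusion_index_pct": ground_truth.true_fusion_index_pct,
            "true_nuclei_count": ground_truth.true_nuclei_count,
        }
        tifffile.imwrite(
            bundle_dir / "fiber_labels.tif",
            ground_truth.fiber_masks.astype(np.uint16),
        )
    (bundle_dir / "scene.json").write_text(json.dumps(meta, indent=1))
    return bundle_dir


def read_scene_bundle(bundle_dir) -> tuple[Scene, GroundTruth | None]:
    """Read a scene bundle; returns ``(scene, ground_truth_or_None)``."""
    bundle_dir = Path(bundle_dir)
    meta_path = bundle_dir / "scene.json"
    if not meta_path.exists():
        raise FormatError(f"{bundle_dir}: not a scene bundle (missing scene.json)")
    meta = json.loads(meta_path.read_text())
    scene = read_scene(
        bundle_dir / "cytoplasm.tif",
        bundle_dir / "nucleus.tif",
        well_id=meta["well_id"],
        day=int(meta["day"]),
        condition=meta.get("condition", ""),
        field_index=int(meta.get("field_index", 0)),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )
    gt = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        labels = tifffile.imread(bundle_dir / "fiber_labels.tif").astype(np.int32)
        gt = GroundTruth(
            nuclei=[
                TrueNucleus(x=float(x), y=float(y), fiber_id=None if f is None else int(f))
                for x, y, f in g["nuclei"]
            ],
            fiber_masks=labels,
            true_fusion_index_pct=float(g["true_fusion_index_pct"]),
            true_nuclei_count=int(g["true_nuclei_count"]),
        )
    return scene, gt


def results_to_frame(records) -> pd.DataFrame:
    """``records``: iterable of (scene-or-metadata-dict, FusionResult) pairs."""
    rows = []
    for meta, res in records:
        if isinstance(meta, Scene):
            meta = {
                "well_id": meta.well_id,
                "condition": meta.condition,
                "day": meta.day,
                "field_index": meta.field_index,
            }
        rows.append(
            {
                "well_id": meta["well_id"],
                "condition": meta.get("condition", ""),
                "day": meta["day"],
                "field_index": meta.get("field_index", 0),
                "total_nuclei": res.total_nuclei,
                "fused_nuclei": res.fused_nuclei,
                "fusion_index_pct": res.fusion_index_pct,
                "n_fused_fibers": res.n_fused_fibers,
                "mean_fiber_area_px": res.mean_fiber_area_px,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(records, path) -> pd.DataFrame:
    """Write per-scene fusion results as CSV, one row per (well, day, field).

    Floats are serialized with enough digits for an exact round trip
    (``repr``-level precision, well beyond 4 significant digits).
    """
    frame = records if isinstance(records, pd.DataFrame) else results_to_frame(records)
    if frame.empty:
        raise EmptyResultError("no results to write")
    frame.to_csv(Path(path), index=False, float_format="%.12g")
    return frame


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path))
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: result table missing columns {missing}")
    return frame
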