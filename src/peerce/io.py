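"""File-format frontends: slides, masks, coordinate lists, annotations.

Slides are plain RGB rasters in TIFF (via tifffile) or PNG (via imageio);
masks are single-channel 0/255 PNGs; patch coordinates, point annotations
and pathologist scores travel as CSV; tumor regions as GeoJSON polygons.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape

from .cells import CellAnnotation, CellType
from .tissue import SlideImage, StainKind

__all__ = [
    "read_slide",
    "write_mask",
    "read_mask",
    "write_patch_coords",
    "read_patch_coords",
    "read_tumor_rois",
    "read_cell_annotations",
    "write_cell_results",
    "read_pathologist_scores",
]


def read_slide(path, stain_kind: StainKind | str = StainKind.PDL1,
               slide_id: str | None = None) -> SlideImage:
    """Load a TIFF or PNG slide as a working-resolution RGB SlideImage."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[-1] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return SlideImage(pixels=pixels.astype(np.uint8),
                      stain_kind=StainKind(stain_kind),
                      slide_id=slide_id or path.stem)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_patch_coords(locs, slide_id: str, path, patch_size: int = 512) -> None:
    pd.DataFrame([{"slide_id": slide_id, "row": r, "col": c,
                   "patch_size": patch_size} for (r, c) in locs]).to_csv(
        Path(path), index=False)


def read_patch_coords(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def read_tumor_rois(path) -> list:
    """Read tumor-region polygons from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    geoms = []
    for feat in data.get("features", []):
        geoms.append(shapely_shape(feat["geometry"]))
    return geoms


def read_cell_annotations(path) -> list[CellAnnotation]:
    """Read point cell annotations (columns x, y, label)."""
    df = pd.read_csv(Path(path))
    return [CellAnnotation(x=float(r.x), y=float(r.y), label=CellType(r.label))
            for r in df.itertuples()]


def write_cell_results(cells_per_patch: dict, path) -> None:
    """Per-cell results CSV: patch, cell id, type, class probabilities."""
    rows = []
    for loc, cells in cells_per_patch.items():
        for i, cell in enumerate(cells):
            p = cell.class_probs
            rows.append({
                "patch_id": f"{loc[0]}_{loc[1]}", "cell_id": i,
                "type": cell.assigned_type.value,
                "prob_tcpos": round(float(p[0]), 6),
                "prob_tcneg": round(float(p[1]), 6),
                "prob_oc": round(float(p[2]), 6),
                "source_branch": cell.source_branch.value,
            })
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_pathologist_scores(path) -> pd.DataFrame:
    """Read pathologist TPS table (patient_id, rater_id, tps[, revised_tps])."""
    df = pd.read_csv(Path(path))
    required = {"patient_id", "rater_id", "tps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pathologist table missing columns: {sorted(missing)}")
    return df
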