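"""Synthetic IHC-like slide generator with exact ground truth.

Real PD-L1 slides are private clinical data, so every pipeline stage is
exercised on generated mini-slides that emulate the salient features of
DAB-stained tissue:

* white glass background, optionally with a near-black scan-edge band;
* tissue as pale-pink textured blobs, with tumor regions rendered slightly
  more eosinophilic and far more cellular than stroma;
* nuclei as dark blue-purple ellipses (nominal diameter ~15 px); other
  (non-tumor) cells get smaller, darker, hyperchromatic nuclei, as
  lymphocyte-like cells are typically smaller than carcinoma cells;
* PD-L1 positive tumor cells carry a brown (DAB-like) membrane ring whose
  grayscale intensity is deliberately close to nuclear chromatin — the
  failure mode that motivates the hematoxylin-transform fallback branch.

Ground truth (tissue mask, tumor polygons, per-cell masks and types, cell
counts, realized TPS) is known exactly by construction.  Tumor cells are
placed only inside full 512-px tiles whose tumor fraction is at least 0.7,
so that a correct patch-selection stage (threshold 0.6 on mean tumor
likelihood) necessarily captures every tumor cell and slide-level TPS is
recoverable from patch-level processing without boundary losses.

A pathologist simulator adds configurable over-/under-scoring bias and
Gaussian noise to true scores, for exercising the concordance layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon, mapping

from skimage.draw import ellipse as draw_ellipse

from .cells import CellType
from .tps import CellCounts, compute_tps

__all__ = [
    "SyntheticSlideSpec",
    "SyntheticGroundTruth",
    "generate_slide",
    "export_annotations",
    "simulate_pathologists",
]

PATCH = 512

# palette (R, G, B); luma of tissue must stay below the Otsu upper bound
COLOR_BG = np.array([255.0, 255.0, 255.0])
COLOR_STROMA = np.array([225.0, 198.0, 210.0])
COLOR_TUMOR_TISSUE = np.array([222.0, 185.0, 200.0])
COLOR_NUCLEUS = np.array([92.0, 72.0, 142.0])       # tumor-cell nucleus
COLOR_OC_NUCLEUS = np.array([45.0, 38.0, 92.0])     # small hyperchromatic
COLOR_DAB = np.array([135.0, 85.0, 40.0])           # brown membrane stain

#: minimum tumor fraction of a tile for tumor-cell placement; above the
#: 0.6 selection threshold so every tumor cell sits in a selectable patch
TILE_CORE_FRACTION = 0.7


@dataclass
class SyntheticSlideSpec:
    """Recipe for one synthetic slide (all sizes in working-res pixels)."""

    canvas_size: tuple[int, int] = (3072, 3072)
    tissue_blobs: int = 3
    blob_semiaxis_range: tuple[float, float] = (500.0, 900.0)
    tumor_fraction: float = 0.5
    n_cells: int = 400
    true_tps: float = 25.0
    oc_fraction: float = 0.3
    nucleus_diameter_px: float = 15.0
    stain_jitter: float = 0.05
    texture_sd: float = 6.0
    black_edge: bool = False
    black_edge_width: int = 48
    rng_seed: int = 0
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.true_tps <= 100:
            raise ValueError("true_tps must lie in [0, 100]")
        if not 0 <= self.oc_fraction <= 1:
            raise ValueError("oc_fraction must lie in [0, 1]")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Exact per-slide ground truth emitted alongside the rendered image."""

    tissue_mask: np.ndarray
    tumor_mask: np.ndarray
    tumor_polygons: list[Polygon]
    cells: list[dict]                 # {id, x, y, type}
    cell_labels: np.ndarray           # int32 label image of nucleus masks
    type_raster: np.ndarray           # per-pixel class: 0/1/2 cells, 3 background
    counts: CellCounts = field(default_factory=CellCounts)
    true_tps: float | None = None


def _ellipse_polygon(cy: float, cx: float, ry: float, rx: float, theta: float,
                     n: int = 64) -> Polygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    y = ry * np.cos(t)
    x = rx * np.sin(t)
    yr = cy + y * np.cos(theta) - x * np.sin(theta)
    xr = cx + y * np.sin(theta) + x * np.cos(theta)
    return Polygon(zip(xr, yr))  # shapely uses (x, y)


def _place_blobs(spec: SyntheticSlideSpec, rng: np.random.Generator):
    """Sample non-overlapping ellipse blobs (center, semi-axes, rotation)."""
    h, w = spec.canvas_size
    blobs = []
    for _ in range(spec.tissue_blobs):
        lo, hi = spec.blob_semiaxis_range
        for attempt in range(300):
            ry = rng.uniform(lo, hi)
            rx = rng.uniform(lo, hi)
            r = max(ry, rx)
            if 2 * r + 20 > min(h, w):
                ry, rx = ry * 0.8, rx * 0.8
                r = max(ry, rx)
            cy = rng.uniform(r + 10, h - r - 10)
            cx = rng.uniform(r + 10, w - r - 10)
            if all(np.hypot(cy - b[0], cx - b[1]) > r + max(b[2], b[3]) + 10
                   for b in blobs):
                blobs.append((cy, cx, ry, rx, rng.uniform(0, np.pi)))
                break
            if attempt % 60 == 59:       # canvas too crowded: shrink and retry
                lo, hi = lo * 0.85, hi * 0.85
    return blobs


def _inner_region(mask: np.ndarray, margin: float, step: int = 4) -> np.ndarray:
    """Pixels of ``mask`` at least ``margin`` px from its boundary.

    The distance transform runs on a ``step``-downsampled mask (with a
    conservative allowance for the resulting quantization) — placement
    margins here have several pixels of slack.
    """
    small = mask[::step, ::step]
    dist = ndi.distance_transform_edt(small) * step
    inner_small = dist > margin + step * 1.5
    inner = np.repeat(np.repeat(inner_small, step, axis=0), step, axis=1)
    return inner[: mask.shape[0], : mask.shape[1]] & mask


def _sample_points(region: np.ndarray, n: int, spacing: float,
                   rng: np.random.Generator, taken: list[tuple[float, float]]
                   ) -> list[tuple[int, int]]:
    """Rejection-sample n points in ``region`` with minimum center spacing."""
    ys, xs = np.nonzero(region)
    if len(ys) == 0 and n > 0:
        raise ValueError("requested cells exceed packable area: no eligible pixels")
    # random sequential packing of spacing-disks jams well below full
    # coverage; refuse clearly impossible requests before sampling
    if n > 0 and n * np.pi * (spacing / 2.0) ** 2 * 0.3 > len(ys):
        raise ValueError(
            f"requested cells exceed packable area: {n} cells in {len(ys)} px")
    pts: list[tuple[int, int]] = []
    bins: dict[tuple[int, int], list[tuple[float, float]]] = {}
    cell_sz = max(spacing, 1.0)

    def _ok(y, x):
        by, bx = int(y // cell_sz), int(x // cell_sz)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for (py, px) in bins.get((by + dy, bx + dx), ()):
                    if (py - y) ** 2 + (px - x) ** 2 < spacing ** 2:
                        return False
        return True

    def _add(y, x):
        bins.setdefault((int(y // cell_sz), int(x // cell_sz)), []).append((y, x))

    for (y, x) in taken:
        _add(y, x)
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 100 * max(n, 1) + 1000:
            raise ValueError(
                f"requested cells exceed packable area: placed {len(pts)} of {n}")
        i = rng.integers(len(ys))
        y, x = int(ys[i]), int(xs[i])
        if _ok(y, x):
            _add(y, x)
            pts.append((y, x))
    return pts


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render one synthetic slide and its exact ground truth.

    Deterministic for a fixed ``spec.rng_seed``: identical spec gives a
    byte-identical image and ground truth.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.canvas_size
    img = np.empty((h, w, 3), dtype=np.float32)
    img[...] = COLOR_BG

    # -- tissue and tumor regions -------------------------------------
    blobs = _place_blobs(spec, rng)
    blob_masks = []
    for (cy, cx, ry, rx, th) in blobs:
        m = np.zeros((h, w), dtype=bool)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=th)
        m[rr, cc] = True
        blob_masks.append(m)
    tissue_mask = np.zeros((h, w), dtype=bool)
    for m in blob_masks:
        tissue_mask |= m

    areas = [m.sum() for m in blob_masks]
    order = np.argsort(areas)[::-1]
    tumor_mask = np.zeros((h, w), dtype=bool)
    tumor_polygons: list[Polygon] = []
    tissue_area = max(tissue_mask.sum(), 1)
    if spec.tumor_fraction > 0 and blobs:
        for i in order:
            if tumor_mask.sum() / tissue_area >= spec.tumor_fraction:
                break
            tumor_mask |= blob_masks[i]
            cy, cx, ry, rx, th = blobs[i]
            tumor_polygons.append(_ellipse_polygon(cy, cx, ry, rx, th))

    noise = rng.normal(0.0, spec.texture_sd, size=(h, w, 1)).astype(np.float32)
    stroma = tissue_mask & ~tumor_mask
    img[stroma] = COLOR_STROMA + noise[stroma]
    img[tumor_mask] = COLOR_TUMOR_TISSUE + noise[tumor_mask]

    # -- cell placement ------------------------------------------------
    rad = spec.nucleus_diameter_px / 2.0
    ring_w = 3
    margin = rad * 1.2 + ring_w + 2

    n_oc = int(round(spec.oc_fraction * spec.n_cells))
    n_tumor_cells = spec.n_cells - n_oc if tumor_mask.any() else 0
    n_tcpos = int(round(spec.true_tps / 100.0 * n_tumor_cells))

    # tumor cells: restricted to 512-aligned tiles that are mostly tumor
    tiles_r, tiles_c = h // PATCH, w // PATCH
    core = np.zeros((h, w), dtype=bool)
    if tiles_r and tiles_c and n_tumor_cells:
        tm = tumor_mask[: tiles_r * PATCH, : tiles_c * PATCH]
        frac = tm.reshape(tiles_r, PATCH, tiles_c, PATCH).mean(axis=(1, 3))
        keep = frac >= TILE_CORE_FRACTION
        core[: tiles_r * PATCH, : tiles_c * PATCH] = np.kron(
            keep, np.ones((PATCH, PATCH), dtype=bool))
        core &= _inner_region(tumor_mask, margin)
    tissue_inner = _inner_region(tissue_mask, margin)

    spacing = spec.nucleus_diameter_px
    tumor_pts = _sample_points(core, n_tumor_cells, spacing, rng, [])
    oc_pts = _sample_points(tissue_inner, n_oc, spacing, rng, tumor_pts)

    tumor_types = [CellType.TCPOS] * n_tcpos \
        + [CellType.TCNEG] * (n_tumor_cells - n_tcpos)
    tumor_types = [tumor_types[i] for i in rng.permutation(n_tumor_cells)]

    # -- render cells ---------------------------------------------------
    cell_labels = np.zeros((h, w), dtype=np.int32)
    type_raster = np.full((h, w), 3, dtype=np.uint8)   # 3 = background
    cells: list[dict] = []
    counts = CellCounts()

    def _jitter(color: np.ndarray) -> np.ndarray:
        return np.clip(color * (1 + rng.normal(0, spec.stain_jitter, 3)), 0, 255)

    cid = 0
    for (y, x), ctype in list(zip(tumor_pts, tumor_types)) + \
            [(p, CellType.OC) for p in oc_pts]:
        cid += 1
        scale = 0.6 if ctype == CellType.OC else 1.0
        ry = rad * scale * rng.uniform(0.85, 1.15)
        rx = rad * scale * rng.uniform(0.85, 1.15)
        th = rng.uniform(0, np.pi)
        if ctype == CellType.TCPOS:
            # brown membrane ring, drawn beneath the nucleus
            rr, cc = draw_ellipse(y, x, ry + ring_w, rx + ring_w, shape=(h, w),
                                  rotation=th)
            img[rr, cc] = _jitter(COLOR_DAB)
            nucleus_color = 0.75 * COLOR_NUCLEUS + 0.25 * COLOR_DAB
        elif ctype == CellType.TCNEG:
            nucleus_color = COLOR_NUCLEUS
        else:
            nucleus_color = COLOR_OC_NUCLEUS
        rr, cc = draw_ellipse(y, x, ry, rx, shape=(h, w), rotation=th)
        img[rr, cc] = _jitter(nucleus_color)
        cell_labels[rr, cc] = cid
        class_idx = {"TC+": 0, "TC-": 1, "OC": 2}[ctype.value]
        type_raster[rr, cc] = class_idx
        cells.append({"id": cid, "x": int(x), "y": int(y), "type": ctype.value})
        if ctype == CellType.TCPOS:
            counts = counts + CellCounts(1, 0, 0)
        elif ctype == CellType.TCNEG:
            counts = counts + CellCounts(0, 1, 0)
        else:
            counts = counts + CellCounts(0, 0, 1)

    if spec.black_edge:
        b = spec.black_edge_width
        edge = np.zeros((h, w), dtype=bool)
        edge[:b], edge[-b:], edge[:, :b], edge[:, -b:] = True, True, True, True
        img[edge] = rng.integers(0, 16, size=(int(edge.sum()), 3))

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gt = SyntheticGroundTruth(
        tissue_mask=tissue_mask, tumor_mask=tumor_mask,
        tumor_polygons=tumor_polygons, cells=cells, cell_labels=cell_labels,
        type_raster=type_raster, counts=counts, true_tps=compute_tps(counts))
    return image, gt


def export_annotations(gt: SyntheticGroundTruth, out_dir) -> dict[str, Path]:
    """Write ground truth in the formats the pipeline consumes.

    Produces ``tumor_rois.geojson`` (FeatureCollection of tumor polygons),
    ``cells.csv`` (x, y, label point annotations), ``tissue_mask.png``
    (0/255 single channel) and ``truth.json`` (counts and realized TPS).
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    features = [{"type": "Feature", "properties": {"name": f"tumor_roi_{i}"},
                 "geometry": mapping(p)} for i, p in enumerate(gt.tumor_polygons)]
    paths["tumor_rois"] = out / "tumor_rois.geojson"
    paths["tumor_rois"].write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))

    df = pd.DataFrame([{"x": c["x"], "y": c["y"], "label": c["type"]}
                       for c in gt.cells])
    paths["cells"] = out / "cells.csv"
    df.to_csv(paths["cells"], index=False)

    paths["tissue_mask"] = out / "tissue_mask.png"
    iio.imwrite(paths["tissue_mask"], (gt.tissue_mask * np.uint8(255)))

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps({
        "n_tcpos": gt.counts.n_tcpos, "n_tcneg": gt.counts.n_tcneg,
        "n_oc": gt.counts.n_oc, "true_tps": gt.true_tps}))
    return paths


def simulate_pathologists(true_tps_list, n_raters: int = 3, noise_sd: float = 5.0,
                          bias_rules: dict | None = None, seed: int = 0
                          ) -> pd.DataFrame:
    """Simulate pathologist TPS estimates: truth + bias + Gaussian noise.

    ``bias_rules`` maps either a case index (bias applied for every rater)
    or a ``(case_index, rater_index)`` pair to a percentage-point bias,
    emulating systematic over-/under-scoring of individual cases.  Scores
    are clipped to [0, 100].  Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    bias_rules = bias_rules or {}
    rows = []
    for i, t in enumerate(true_tps_list):
        for r in range(n_raters):
            bias = bias_rules.get((i, r), bias_rules.get(i, 0.0))
            score = float(np.clip(t + bias + rng.normal(0.0, noise_sd), 0.0, 100.0))
            rows.append({"patient_id": f"case_{i:03d}", "rater_id": f"rater_{r}",
                         "tps": score})
    return pd.DataFrame(rows)
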