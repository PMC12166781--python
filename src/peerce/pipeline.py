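"""End-to-end slide scoring: tissue → tumor patches → cells → TPS.

Ties the stage modules together behind one function, :func:`score_slide`,
which takes a working-resolution slide plus the three backends (tumor
pixel classifier, nucleus instance detector, cell-typing classifier, and
optionally a hematoxylin transform) and returns the slide's aggregated
cell counts and TPS together with per-patch diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from . import cells as _cells
from . import tissue as _tissue
from . import tumor as _tumor
from .nets import softmax_channels
from .tps import CellCounts, SlideScore, compute_tps

__all__ = [
    "SlideResult",
    "rasterize_polygons",
    "true_tumor_patches",
    "extract_patch",
    "score_slide",
]


@dataclass
class SlideResult:
    """Everything the pipeline derived from one slide."""

    slide_score: SlideScore
    grid: _tissue.TissueGrid
    patch_scores: list[_tumor.TumorPatchScore]
    selected: list[_tumor.TumorPatchScore]
    cells_per_patch: dict = field(default_factory=dict)

    @property
    def tps(self) -> float | None:
        return self.slide_score.tps_percent


def rasterize_polygons(polygons, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the union of shapely polygons (x→col, y→row)."""
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw_polygon(np.asarray(ys), np.asarray(xs), shape=shape)
        mask[rr, cc] = True
    return mask


def true_tumor_patches(tumor_mask: np.ndarray, locations,
                       min_fraction: float = 0.5,
                       patch_size: int = _tissue.PATCH_SIZE) -> set:
    """Patches whose ground-truth tumor pixel fraction exceeds ``min_fraction``."""
    out = set()
    for (r, c) in locations:
        sub = tumor_mask[r:r + patch_size, c:c + patch_size]
        if sub.size and sub.mean() > min_fraction:
            out.add((r, c))
    return out


def extract_patch(image: np.ndarray, loc: tuple[int, int],
                  patch_size: int = _tissue.PATCH_SIZE) -> np.ndarray:
    r, c = loc
    return np.asarray(image)[r:r + patch_size, c:c + patch_size]


def score_slide(image: np.ndarray, *, tumor_backend, cell_backend,
                instance_backend, hema_backend=None,
                masking_cfg: _tissue.MaskingConfig | None = None,
                threshold: float = _tumor.TUMOR_THRESHOLD,
                min_count: int = _tumor.MIN_TUMOR_PATCHES,
                stain_kind: _tissue.StainKind = _tissue.StainKind.PDL1,
                slide_id: str = "", patient_id: str = "") -> SlideResult:
    """Run the full TPS pipeline on one working-resolution RGB slide.

    Stages: tissue masking and patch enumeration; per-patch tumor scoring
    and thresholded selection (with the ≥``min_count`` fallback); nucleus
    instance detection with the hematoxylin-transform fallback; per-cell
    4-class softmax averaging; aggregation of TC+/TC- counts into the
    slide TPS.  Slides with no detected tumor cells get an undefined
    (None) TPS.
    """
    image = np.asarray(image)
    slide = _tissue.SlideImage(pixels=image, stain_kind=stain_kind, slide_id=slide_id)
    grid = _tissue.tissue_grid(slide, masking_cfg)

    counts = CellCounts()
    patch_scores: list[_tumor.TumorPatchScore] = []
    selected: list[_tumor.TumorPatchScore] = []
    cells_per_patch: dict = {}

    if grid.patch_locations:
        patch_scores = _tumor.score_patches(
            tumor_backend,
            ((loc, extract_patch(image, loc)) for loc in grid.patch_locations))
        selected = _tumor.select_tumor_patches(patch_scores, threshold, min_count)
        for ps in selected:
            patch = extract_patch(image, ps.location)
            masks, branch = _cells.detect_instances_with_fallback(
                patch, instance_backend, hema_backend, location=ps.location)
            if not masks:
                cells_per_patch[ps.location] = []
                continue
            raw = cell_backend.predict_raw(patch, location=ps.location)
            sm = softmax_channels(raw, axis=-1)
            typed = _cells.classify_cells(sm, masks, branch)
            cells_per_patch[ps.location] = typed
            for cell in typed:
                if cell.assigned_type == _cells.CellType.TCPOS:
                    counts = counts + CellCounts(1, 0, 0)
                elif cell.assigned_type == _cells.CellType.TCNEG:
                    counts = counts + CellCounts(0, 1, 0)
                else:
                    counts = counts + CellCounts(0, 0, 1)

    score = SlideScore(slide_id=slide_id, patient_id=patient_id, counts=counts,
                       tps_percent=compute_tps(counts))
    return SlideResult(slide_score=score, grid=grid, patch_scores=patch_scores,
                       selected=selected, cells_per_patch=cells_per_patch)
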