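"""Reproducible ground-truth recovery experiments on synthetic cohorts.

Two end-to-end experiments validate the pipeline at desk scale:

``oracle_recovery``
    runs the full patch pipeline with oracle backends that emit ground
    truth through the production interfaces (one-hot tumor and cell-type
    score maps, ground-truth nucleus masks).  Any discrepancy between
    recovered and true TPS is then a plumbing defect, not a modeling one;
    by construction the recovered TPS should match exactly.

``learned_recovery``
    trains the toy tumor and cell-typing classifiers on a handful of
    synthetic slides (sparse point annotations rasterized through detected
    instances, exactly as real training data would be) and scores held-out
    slides spanning TPS 0-80%, reporting the mean absolute TPS error and
    the Pearson correlation against ground truth.

Both are deterministic given their seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .backends import (HedHemaTransform, OracleCellBackend,
                       OracleInstanceProvider, OracleTumorBackend,
                       WatershedNucleusDetector)
from .cells import (CELLTYPE_CLASS_WEIGHTS, CellAnnotation, CellType,
                    detect_instances_with_fallback,
                    rasterize_point_annotations, train_celltype_backend)
from .nets import TrainConfig
from .pipeline import extract_patch, score_slide
from .synth import SyntheticSlideSpec, generate_slide
from .tissue import SlideImage, tissue_grid
from .tumor import train_tumor_backend

__all__ = ["oracle_recovery", "learned_recovery", "toy_train_config",
           "HELD_OUT_TPS", "TRAIN_TPS"]

#: held-out slide TPS levels spanning the 0-80% range
HELD_OUT_TPS = (0.0, 9.0, 18.0, 27.0, 36.0, 44.0, 53.0, 62.0, 71.0, 80.0)
#: TPS levels of the toy training slides
TRAIN_TPS = (10.0, 30.0, 55.0, 75.0)
#: annotated cells per training patch (real annotation density is ~20-30)
ANNOTATIONS_PER_PATCH = 25


def toy_train_config(seed: int = 0, n_classes: int = 2) -> TrainConfig:
    """Toy-scale trainer settings: few epochs, subsampled pixels, flips only.

    The full-scale defaults (50/25 epochs, full augmentation) are overkill
    for the cleanly separable synthetic palette; a dozen epochs converge.
    """
    return TrainConfig(
        epochs=12, initial_lr=0.01, pixels_per_patch=3000,
        affine=False, color_jitter=False, rng_seed=seed,
        class_weights=CELLTYPE_CLASS_WEIGHTS if n_classes == 4 else None)


def _slide_seed(seed: int, i: int) -> int:
    return (seed * 7919 + i) % (2 ** 31)


def oracle_recovery(seed: int = 0, tps_levels=HELD_OUT_TPS) -> dict:
    """Oracle-backend end-to-end TPS recovery on synthetic slides."""
    pairs = []
    for i, tps in enumerate(tps_levels):
        spec = SyntheticSlideSpec(true_tps=float(tps),
                                  rng_seed=_slide_seed(seed, 100 + i))
        image, gt = generate_slide(spec)
        res = score_slide(
            image,
            tumor_backend=OracleTumorBackend(gt.tumor_mask),
            cell_backend=OracleCellBackend(gt.type_raster),
            instance_backend=OracleInstanceProvider(gt.cell_labels))
        pairs.append((gt.true_tps, res.tps))
    errs = [abs(p - t) for t, p in pairs]
    return {"pairs": pairs, "max_abs_error_pp": float(max(errs)),
            "n_slides": len(pairs)}


def _training_set(seed: int, patches_per_slide: int = 10):
    """Build toy training patches with tumor masks and sparse cell labels."""
    det = WatershedNucleusDetector()
    hema = HedHemaTransform()
    rng = np.random.default_rng(_slide_seed(seed, 7))
    patches, tumor_labels, cell_labels = [], [], []
    for i, tps in enumerate(TRAIN_TPS):
        spec = SyntheticSlideSpec(true_tps=float(tps),
                                  rng_seed=_slide_seed(seed, 500 + i))
        image, gt = generate_slide(spec)
        grid = tissue_grid(SlideImage(pixels=image))
        locs = grid.patch_locations
        take = rng.choice(len(locs), size=min(patches_per_slide, len(locs)),
                          replace=False)
        for j in take:
            loc = locs[j]
            patch = extract_patch(image, loc)
            patches.append(patch)
            tumor_labels.append(
                extract_patch(gt.tumor_mask, loc).astype(np.uint8))
            anns = [CellAnnotation(c["x"] - loc[1], c["y"] - loc[0],
                                   CellType(c["type"]))
                    for c in gt.cells
                    if loc[0] <= c["y"] < loc[0] + 512
                    and loc[1] <= c["x"] < loc[1] + 512]
            anns = anns[:ANNOTATIONS_PER_PATCH]
            masks, _ = detect_instances_with_fallback(patch, det, hema)
            with warnings.catch_warnings():
                # merged instances can catch two marks; nearest-point rule applies
                warnings.simplefilter("ignore", UserWarning)
                cell_labels.append(
                    rasterize_point_annotations(anns, patch.shape[:2], masks))
    return patches, tumor_labels, cell_labels


def learned_recovery(seed: int = 0, tps_levels=HELD_OUT_TPS) -> dict:
    """Train toy backends on 40 synthetic patches; score held-out slides."""
    patches, tumor_labels, cell_labels = _training_set(seed)
    tumor_net = train_tumor_backend(patches, tumor_labels,
                                    toy_train_config(seed, n_classes=2))
    cell_net = train_celltype_backend(patches, cell_labels,
                                      toy_train_config(seed, n_classes=4))
    det = WatershedNucleusDetector()
    hema = HedHemaTransform()
    pairs = []
    for i, tps in enumerate(tps_levels):
        spec = SyntheticSlideSpec(true_tps=float(tps),
                                  rng_seed=_slide_seed(seed, 900 + i))
        image, gt = generate_slide(spec)
        res = score_slide(image, tumor_backend=tumor_net, cell_backend=cell_net,
                          instance_backend=det, hema_backend=hema)
        pairs.append((gt.true_tps, res.tps))
    defined = [(t, p) for t, p in pairs if p is not None]
    errs = [abs(p - t) for t, p in defined]
    t_arr = np.array([t for t, _ in defined])
    p_arr = np.array([p for _, p in defined])
    r = float(np.corrcoef(t_arr, p_arr)[0, 1]) if len(defined) >= 3 else None
    return {"pairs": pairs, "n_train_patches": len(patches),
            "mean_abs_error_pp": float(np.mean(errs)),
            "max_abs_error_pp": float(np.max(errs)),
            "pearson_r": r, "n_slides": len(pairs)}
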