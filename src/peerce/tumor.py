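"""Tumor patch detection: scoring, thresholded selection, training, metrics.

Each candidate tissue patch is pushed through a 2-class pixel classifier
(non-tumor, tumor).  Per-pixel softmax is applied and the patch's *tumor
score* is the mean of the tumor-probability channel, a value in [0, 1].
Patches scoring above 0.6 are kept; when a slide yields fewer than 10 such
patches the selection falls back to the 10 best-scoring patches so that
downstream cell counting always has material to work with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import IGNORE_LABEL, PixelSoftmaxNet, TrainConfig, softmax_channels

__all__ = [
    "TumorPatchScore",
    "tumor_score",
    "score_patches",
    "select_tumor_patches",
    "train_tumor_backend",
    "evaluate_detection",
    "TrainConfig",
]

TUMOR_THRESHOLD = 0.6
MIN_TUMOR_PATCHES = 10


@dataclass
class TumorPatchScore:
    """Mean tumor likelihood of one patch, plus its selection outcome."""

    location: tuple[int, int]
    score: float
    selected: bool = False
    threshold_applied: float = TUMOR_THRESHOLD


def tumor_score(raw_scores: np.ndarray) -> float:
    """Mean per-pixel softmax probability of the tumor channel.

    ``raw_scores`` is an (H, W, 2) map of raw class scores with channel 1
    the tumor class.  Softmax is applied pixelwise, then the tumor channel
    is averaged over all pixels.
    """
    raw = np.asarray(raw_scores, dtype=np.float64)
    if raw.ndim != 3 or raw.shape[2] != 2:
        raise ValueError("expected an (H, W, 2) raw score map")
    probs = softmax_channels(raw, axis=-1)
    return float(probs[..., 1].mean())


def score_patches(backend, patch_iter) -> list[TumorPatchScore]:
    """Score an iterable of ``(location, rgb_patch)`` pairs with a backend."""
    out = []
    for loc, patch in patch_iter:
        raw = backend.predict_raw(patch, location=loc)
        out.append(TumorPatchScore(location=tuple(loc), score=tumor_score(raw)))
    return out


def select_tumor_patches(scores: list[TumorPatchScore],
                         threshold: float = TUMOR_THRESHOLD,
                         min_count: int = MIN_TUMOR_PATCHES) -> list[TumorPatchScore]:
    """Select tumor patches by score with a minimum-count fallback.

    All patches scoring strictly above ``threshold`` are selected.  If that
    yields fewer than ``min_count`` patches, the threshold is effectively
    lowered by taking the top ``min_count`` patches by score (ties broken
    by row-major coordinate order); a slide with fewer than ``min_count``
    patches in total contributes all of them.  Each returned record has
    ``selected=True`` and ``threshold_applied`` set to the smallest
    selected score.
    """
    if not scores:
        raise ValueError("empty score list")
    above = [s for s in scores if s.score > threshold]
    if len(above) >= min_count:
        chosen = above
    else:
        ranked = sorted(scores, key=lambda s: (-s.score, s.location))
        chosen = ranked[: min(min_count, len(scores))]
    applied = min(s.score for s in chosen)
    chosen_locs = {s.location for s in chosen}
    out = []
    for s in scores:  # preserve input order
        sel = s.location in chosen_locs
        out.append(TumorPatchScore(s.location, s.score, selected=sel,
                                   threshold_applied=applied))
    return [s for s in out if s.selected]


def train_tumor_backend(patches: list[np.ndarray], tumor_masks: list[np.ndarray],
                        cfg: TrainConfig | None = None) -> PixelSoftmaxNet:
    """Train the 2-class tumor/non-tumor pixel classifier.

    ``tumor_masks`` are per-pixel boolean maps (True = tumor), typically
    rasterized from pathologist tumor-region polygons.
    """
    cfg = cfg or TrainConfig(epochs=50)
    labels = [np.asarray(m, dtype=np.uint8) for m in tumor_masks]
    if not any((l != IGNORE_LABEL).any() and l.size for l in labels):
        raise ValueError("no labeled pixels")
    net = PixelSoftmaxNet(n_classes=2, config=cfg)
    net.fit([np.asarray(p) for p in patches], labels, cfg)
    return net


def evaluate_detection(selected: set, truth: set,
                       pred_masks: list[np.ndarray] | None = None,
                       truth_masks: list[np.ndarray] | None = None) -> dict:
    """Patch-level precision/recall and pixel-level Dice.

    ``selected`` and ``truth`` are sets of patch locations; the optional
    mask lists are aligned pairs of boolean pixel masks pooled into one
    aggregate Dice coefficient 2|A∩B| / (|A| + |B|).  With an empty truth
    set, recall is undefined and reported as ``None``.
    """
    selected, truth = set(selected), set(truth)
    tp = len(selected & truth)
    precision = tp / len(selected) if selected else (1.0 if not truth else 0.0)
    recall = tp / len(truth) if truth else None

    dice = None
    if pred_masks is not None and truth_masks is not None:
        if len(pred_masks) != len(truth_masks):
            raise ValueError("pred/truth mask lists must align")
        inter = sum(int((np.asarray(a, bool) & np.asarray(b, bool)).sum())
                    for a, b in zip(pred_masks, truth_masks))
        total = sum(int(np.asarray(a, bool).sum()) + int(np.asarray(b, bool).sum())
                    for a, b in zip(pred_masks, truth_masks))
        dice = 2.0 * inter / total if total else None
    return {"precision": precision, "recall": recall, "dice": dice}
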