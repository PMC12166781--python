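"""Cell instance detection with stain-transform fallback, and cell typing.

Nucleus detection on PD-L1 slides is complicated by strong DAB staining:
brown membrane signal converted to grayscale looks much like bluish
chromatin, so detectors under-segment heavily stained patches.  The
pipeline therefore runs detection twice — on the original patch and, when
a hematoxylin-transform backend is configured, on a hematoxylin-only
rendering — and keeps the branch that finds strictly more cells (ties go
to the original patch).

Each detected instance is then typed by overlaying its mask on a 4-class
per-pixel softmax map (TC+, TC-, OC, background), averaging the softmax
vectors over the mask, discarding the background entry (an outline contains
only cellular material), and taking the argmax of the remaining three.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nets import IGNORE_LABEL, PixelSoftmaxNet, TrainConfig

__all__ = [
    "CellType",
    "SourceBranch",
    "CellInstance",
    "CellAnnotation",
    "detect_instances_with_fallback",
    "rasterize_point_annotations",
    "train_celltype_backend",
    "classify_cells",
    "CELLTYPE_CLASS_WEIGHTS",
]

#: loss weights for (TC+, TC-, OC, background): the background class
#: dominates pixel counts and is downweighted accordingly
CELLTYPE_CLASS_WEIGHTS = (1.0, 1.0, 1.0, 0.0004)

#: class index layout of the 4-class cell-typing head
CLASS_INDEX = {"TC+": 0, "TC-": 1, "OC": 2, "background": 3}


class CellType(str, enum.Enum):
    TCPOS = "TC+"
    TCNEG = "TC-"
    OC = "OC"


class SourceBranch(str, enum.Enum):
    ORIGINAL = "original"
    HEMA_TRANSFORMED = "hema_transformed"


@dataclass
class CellInstance:
    """One detected nucleus with its typing result."""

    mask: np.ndarray
    source_branch: SourceBranch = SourceBranch.ORIGINAL
    class_probs: np.ndarray | None = None   # (TC+, TC-, OC, background)
    assigned_type: CellType | None = None


@dataclass
class CellAnnotation:
    """A point-marked cell: coordinates plus class label, no outline."""

    x: float
    y: float
    label: CellType


def _detect(inst, patch: np.ndarray, location):
    try:
        return inst.detect(patch, location=location)
    except TypeError:  # backend without a location parameter
        return inst.detect(patch)


def detect_instances_with_fallback(patch: np.ndarray, inst, hema=None,
                                   *, location=None
                                   ) -> tuple[list[np.ndarray], SourceBranch]:
    """Run instance detection on the original and hema-transformed patch.

    Returns the masks of whichever branch detected strictly more cells;
    on a tie (including zero/zero) the original branch wins.  Without a
    hema backend only the original branch runs.
    """
    patch = np.asarray(patch)
    if hema is None:
        return _detect(inst, patch, location), SourceBranch.ORIGINAL
    err_orig = err_hema = None
    try:
        masks_orig = _detect(inst, patch, location)
    except Exception as e:  # keep going: the other branch may still work
        masks_orig, err_orig = None, e
    try:
        masks_hema = _detect(inst, np.asarray(hema.transform(patch)), location)
    except Exception as e:
        masks_hema, err_hema = None, e
    if masks_orig is None and masks_hema is None:
        raise RuntimeError(
            f"instance detection failed on both branches: {err_orig!r} / {err_hema!r}")
    if masks_orig is None:
        return masks_hema, SourceBranch.HEMA_TRANSFORMED
    if masks_hema is None:
        return masks_orig, SourceBranch.ORIGINAL
    if len(masks_hema) > len(masks_orig):
        return masks_hema, SourceBranch.HEMA_TRANSFORMED
    return masks_orig, SourceBranch.ORIGINAL


def rasterize_point_annotations(annotations: list[CellAnnotation],
                                shape: tuple[int, int],
                                instances: list[np.ndarray] | None = None,
                                radius: int = 7) -> np.ndarray:
    """Turn sparse point marks into a per-pixel training label map.

    A marked point labels the detected instance mask containing it when one
    is available, and otherwise a disk of ``radius`` pixels around the
    point.  Detected instances that received no mark are cells of unknown
    type: their pixels carry the ignore-label and contribute nothing to
    the loss.  All remaining pixels are labeled background — the class the
    tiny 0.0004 loss weight exists for.  Where claims overlap, the nearest
    annotation point wins; two annotations of different classes landing on
    one instance raise a warning (nearest point keeps the instance).
    """
    h, w = shape
    labels = np.full((h, w), CLASS_INDEX["background"], dtype=np.uint8)
    if instances:
        for m in instances:  # unannotated cells: masked out of the loss
            labels[np.asarray(m, dtype=bool)] = IGNORE_LABEL
    dist = np.full((h, w), np.inf)
    yy, xx = np.mgrid[0:h, 0:w]

    claimed_by: dict[int, CellType] = {}
    for ann in annotations:
        x, y = int(round(ann.x)), int(round(ann.y))
        if not (0 <= y < h and 0 <= x < w):
            raise ValueError(f"annotation ({ann.x}, {ann.y}) outside patch bounds {shape}")
        region = None
        if instances:
            for k, m in enumerate(instances):
                if m[y, x]:
                    if k in claimed_by and claimed_by[k] != ann.label:
                        warnings.warn(
                            f"instance {k} marked with conflicting classes "
                            f"({claimed_by[k].value} vs {ann.label.value}); nearest point wins",
                            stacklevel=2)
                    claimed_by[k] = ann.label
                    region = m
                    break
        if region is None:
            region = (yy - y) ** 2 + (xx - x) ** 2 <= radius ** 2
        d = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
        take = region & (d < dist)
        labels[take] = CLASS_INDEX[ann.label.value]
        dist[take] = d[take]
    return labels


def train_celltype_backend(patches: list[np.ndarray], label_maps: list[np.ndarray],
                           cfg: TrainConfig | None = None) -> PixelSoftmaxNet:
    """Train the 4-class cell-typing pixel classifier.

    Label maps use indices 0..3 for TC+/TC-/OC/background plus the
    ignore-label for unannotated pixels.  Background pixels get loss
    weight 0.0004 against 1 for the three cell classes, compensating the
    extreme class imbalance left after masking unannotated pixels.
    """
    cfg = cfg or TrainConfig(epochs=25)
    if cfg.class_weights is None:
        cfg.class_weights = CELLTYPE_CLASS_WEIGHTS
    net = PixelSoftmaxNet(n_classes=4, config=cfg)
    net.fit([np.asarray(p) for p in patches],
            [np.asarray(l, dtype=np.uint8) for l in label_maps], cfg)
    return net


def classify_cells(softmax_map: np.ndarray, instances: list[np.ndarray],
                   source_branch: SourceBranch = SourceBranch.ORIGINAL
                   ) -> list[CellInstance]:
    """Assign a type to every instance from a per-pixel 4-class softmax map.

    The softmax vectors of all pixels inside an instance mask are averaged;
    the background entry is then discarded and the argmax over
    (TC+, TC-, OC) decides the type.  Exact ties resolve by the fixed
    priority TC+ > TC- > OC.
    """
    sm = np.asarray(softmax_map, dtype=np.float64)
    if sm.ndim != 3 or sm.shape[2] != 4:
        raise ValueError("expected an (H, W, 4) softmax map")
    order = [CellType.TCPOS, CellType.TCNEG, CellType.OC]
    out = []
    for m in instances:
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty instance mask")
        probs = sm[m].mean(axis=0)
        idx = int(np.argmax(probs[:3]))  # np.argmax keeps the first maximum
        out.append(CellInstance(mask=m, source_branch=source_branch,
                                class_probs=probs, assigned_type=order[idx]))
    return out
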