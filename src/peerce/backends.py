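"""Pluggable backends: nucleus instance detection and stain transforms.

Two backend contracts are defined here.

``InstanceBackend``
    maps a preprocessed RGB patch to a list of disjoint nucleus masks.
    Preprocessing is grayscale conversion followed by intensity inversion
    (nuclei become bright blobs on a dark background, the polarity most
    nucleus detectors expect).  The default implementation is a classical
    distance-transform watershed tuned by a nominal nucleus diameter.

``HemaTransformBackend``
    maps an IHC RGB patch to a hematoxylin-only rendering.  Strong DAB
    (brown) staining resembles nuclear chromatin once converted to
    grayscale and can confuse nucleus detection; re-rendering the patch
    from the hematoxylin component alone removes the DAB signal.  The
    default implementation uses HED color deconvolution; a learned
    image-to-image translator can be slotted in behind the same contract.

Oracle backends (ground-truth pass-throughs) used to validate the pipeline
plumbing independently of any trained model live here as well.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.color import hed2rgb, rgb2hed
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .tissue import _luma

__all__ = [
    "InstanceBackend",
    "HemaTransformBackend",
    "grayscale_invert",
    "WatershedNucleusDetector",
    "HedHemaTransform",
    "OracleTumorBackend",
    "OracleCellBackend",
    "OracleInstanceProvider",
]


@runtime_checkable
class InstanceBackend(Protocol):
    def detect(self, patch: np.ndarray, *, location=None) -> list[np.ndarray]:
        """Return disjoint boolean nucleus masks for an RGB patch."""
        ...


@runtime_checkable
class HemaTransformBackend(Protocol):
    def transform(self, patch: np.ndarray) -> np.ndarray:
        """Return a hematoxylin-only RGB rendering of an IHC patch."""
        ...


def grayscale_invert(patch: np.ndarray) -> np.ndarray:
    """Grayscale (BT.601 luma) then invert: nuclei bright, background dark."""
    return 255.0 - _luma(np.asarray(patch))


class WatershedNucleusDetector:
    """Classical nucleus instance segmentation.

    Grayscale-inverted intensity is thresholded (Otsu), small specks are
    removed, and touching nuclei are split by a watershed on the distance
    transform seeded at local maxima spaced by roughly one nucleus radius.

    Parameters
    ----------
    diameter : nominal nucleus diameter in pixels (default 15).
    augment : enable test-time augmentation averaging (detection is run on
        the four axis flips and the run with the most instances wins);
        output is then not guaranteed deterministic across library versions,
        so the flag defaults to off.
    """

    def __init__(self, diameter: float = 15.0, augment: bool = False):
        self.diameter = float(diameter)
        self.augment = bool(augment)

    def _detect_once(self, inv: np.ndarray) -> list[np.ndarray]:
        if inv.min() == inv.max():
            return []
        thr = threshold_otsu(inv.astype(np.float64))
        fg = inv > thr
        min_area = max(int(np.pi * (self.diameter / 4.0) ** 2), 4)
        fg = remove_small_objects(fg, max_size=min_area - 1)
        if not fg.any():
            return []
        dist = ndi.distance_transform_edt(fg)
        min_dist = max(int(self.diameter * 0.45), 2)
        peaks = peak_local_max(dist, min_distance=min_dist, labels=cc_label(fg))
        if len(peaks) == 0:
            return []
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        lab = watershed(-dist, markers=markers, mask=fg)
        masks = []
        for i in range(1, lab.max() + 1):
            m = lab == i
            if m.sum() >= min_area:
                masks.append(m)
        return masks

    def detect(self, patch: np.ndarray, *, location=None) -> list[np.ndarray]:
        inv = grayscale_invert(patch)
        if not self.augment:
            return self._detect_once(inv)
        best: list[np.ndarray] = []
        for flipud in (False, True):
            for fliplr in (False, True):
                v = inv[::-1] if flipud else inv
                v = v[:, ::-1] if fliplr else v
                masks = self._detect_once(np.ascontiguousarray(v))
                undone = []
                for m in masks:
                    u = m[::-1] if flipud else m
                    u = u[:, ::-1] if fliplr else u
                    undone.append(np.ascontiguousarray(u))
                if len(undone) > len(best):
                    best = undone
        return best


class HedHemaTransform:
    """Hematoxylin-only re-rendering via HED color deconvolution.

    Decomposes the RGB patch into hematoxylin/eosin/DAB absorbances
    (Ruifrok–Johnston matrix), zeroes the eosin and DAB components, and
    reconstructs RGB.  Synthetic stand-in for a learned IHC-to-hematoxylin
    translator; satisfies the same input/output contract.
    """

    def transform(self, patch: np.ndarray) -> np.ndarray:
        rgb = np.asarray(patch, dtype=np.float64) / 255.0
        hed = rgb2hed(rgb)
        hed[..., 1] = 0.0
        hed[..., 2] = 0.0
        out = hed2rgb(hed)
        return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# oracle backends: emit ground truth through the production interfaces
# ---------------------------------------------------------------------------

_HI, _LO = 10.0, -10.0  # saturated logits for one-hot score maps


class OracleTumorBackend:
    """Emits one-hot tumor/non-tumor scores from a ground-truth tumor mask."""

    def __init__(self, tumor_mask: np.ndarray):
        self.tumor_mask = np.asarray(tumor_mask, dtype=bool)

    def predict_raw(self, patch: np.ndarray, *, location=None) -> np.ndarray:
        if location is None:
            raise ValueError("oracle backend needs the patch location")
        r, c = location
        h, w = patch.shape[:2]
        sub = self.tumor_mask[r:r + h, c:c + w]
        raw = np.full((h, w, 2), _LO)
        raw[..., 0] = np.where(sub, _LO, _HI)
        raw[..., 1] = np.where(sub, _HI, _LO)
        return raw


class OracleCellBackend:
    """Emits one-hot 4-class scores from a ground-truth cell-type raster.

    ``type_raster`` holds, per pixel, 0/1/2 for TC+/TC-/OC and 3 for
    background.
    """

    def __init__(self, type_raster: np.ndarray):
        self.type_raster = np.asarray(type_raster)

    def predict_raw(self, patch: np.ndarray, *, location=None) -> np.ndarray:
        if location is None:
            raise ValueError("oracle backend needs the patch location")
        r, c = location
        h, w = patch.shape[:2]
        sub = self.type_raster[r:r + h, c:c + w]
        raw = np.full((h, w, 4), _LO)
        for k in range(4):
            raw[..., k] = np.where(sub == k, _HI, _LO)
        return raw


class OracleInstanceProvider:
    """Serves ground-truth nucleus masks, assigning each cell to the patch
    containing its mask centroid (cells straddling patch borders are
    counted exactly once)."""

    def __init__(self, cell_label_image: np.ndarray):
        self.labels = np.asarray(cell_label_image)
        ids = np.unique(self.labels)
        self.ids = ids[ids > 0]
        self.centroids = ndi.center_of_mass(self.labels > 0, self.labels, self.ids) \
            if len(self.ids) else []

    def detect(self, patch: np.ndarray, *, location=None) -> list[np.ndarray]:
        if location is None:
            raise ValueError("oracle instance provider needs the patch location")
        r, c = location
        h, w = patch.shape[:2]
        sub = self.labels[r:r + h, c:c + w]
        masks = []
        for i, (cy, cx) in zip(self.ids, self.centroids):
            if r <= cy < r + h and c <= cx < c + w:
                m = sub == i
                if m.any():
                    masks.append(m)
        return masks
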