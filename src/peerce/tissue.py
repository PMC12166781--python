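"""Tissue detection and candidate patch enumeration.

Whole-slide images are far too large to process in one pass, and much of the
canvas is white background (cutting artifacts, empty glass).  This module
locates tissue on a 16x-downscaled view of the slide and enumerates the
full-resolution 512x512 patches that are sufficiently covered by tissue.

The procedure:

1. downscale the working-resolution RGB slide by a factor of 16;
2. push near-black scan-edge pixels to white (slides scanned with a black
   border band otherwise wreck the automatic threshold);
3. build a single thresholding channel — grayscale for PD-L1/DAB slides,
   the eosin channel of an HED color deconvolution for H&E slides;
4. Otsu-threshold the channel, capped by a fixed upper bound so that
   faintly stained slides do not lose tissue to an absurdly high threshold;
5. walk the low-resolution mask in non-overlapping 32x32 tiles (each tile
   corresponds to one 512x512 working-resolution patch), subdivide every
   tile into sixteen 8x8 sub-patches, and accept the tile when more than
   60% of its sub-patches contain at least five tissue pixels.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu

__all__ = [
    "StainKind",
    "SlideImage",
    "MaskingConfig",
    "TissueGrid",
    "downscale_slide",
    "prepare_threshold_channel",
    "compute_tissue_mask",
    "enumerate_tissue_patches",
    "combine_overlap_mask",
    "sample_training_patches",
    "tissue_grid",
]

#: working-resolution patch edge, in pixels
PATCH_SIZE = 512
#: downscale factor between working resolution and the thresholding raster
DOWNSCALE = 16
#: low-resolution tile edge corresponding to one patch
TILE_LOWRES = PATCH_SIZE // DOWNSCALE  # 32
#: low-resolution sub-patch edge
SUBPATCH_LOWRES = 8

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class StainKind(str, enum.Enum):
    """Stain of a slide: PD-L1 immunohistochemistry (DAB) or H&E."""

    PDL1 = "pdl1"
    HE = "he"


class MagnificationLevel(str, enum.Enum):
    NATIVE_40X = "native40x"
    WORKING_20X = "working20x"
    LOWRES = "lowres"


@dataclass
class SlideImage:
    """An RGB slide raster together with its resolution bookkeeping.

    ``downscale_factor`` is relative to the working (20x-equivalent)
    resolution; the thresholding raster always sits at factor 16.
    """

    pixels: np.ndarray
    stain_kind: StainKind = StainKind.PDL1
    magnification_level: MagnificationLevel = MagnificationLevel.WORKING_20X
    downscale_factor: int = 1
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide pixels must be an RGB raster (H, W, 3); got shape {self.pixels.shape}"
            )
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be a positive integer")


@dataclass
class MaskingConfig:
    """Parameters of tissue detection (8-bit intensity scale throughout)."""

    black_edge_cutoff: int = 20
    otsu_upper_bound: float = 220.0
    subpatch_px: int = SUBPATCH_LOWRES
    min_tissue_px_per_subpatch: int = 5
    min_coverage_fraction: float = 0.60
    training_patch_cap: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage_fraction < 1:
            raise ValueError("min_coverage_fraction must lie in (0, 1)")
        if min(self.black_edge_cutoff, self.subpatch_px,
               self.min_tissue_px_per_subpatch, self.training_patch_cap) <= 0:
            raise ValueError("all masking bounds must be positive")


@dataclass
class TissueGrid:
    """Low-resolution tissue mask plus working-resolution patch coordinates."""

    mask: np.ndarray
    threshold_used: float
    patch_locations: list[tuple[int, int]] = field(default_factory=list)
    patch_size_px: int = PATCH_SIZE
    step_lowres_px: int = TILE_LOWRES


def downscale_slide(img: SlideImage, factor: int = DOWNSCALE) -> SlideImage:
    """Downscale a working-resolution slide by ``factor`` (block mean).

    Plain ``factor x factor`` block averaging: sharp features like black
    scan-edge bands keep their intensity instead of being smeared by a
    pre-blur.  Output dimensions are ``ceil(working / factor)``; border
    blocks are edge-replicated to full size.
    """
    if img.downscale_factor != 1:
        raise ValueError("expected a working-resolution slide")
    h, w = img.pixels.shape[:2]
    out_shape = (int(np.ceil(h / factor)), int(np.ceil(w / factor)))
    pad_h, pad_w = out_shape[0] * factor - h, out_shape[1] * factor - w
    padded = np.pad(img.pixels, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
    small = padded.reshape(out_shape[0], factor, out_shape[1], factor, 3) \
        .mean(axis=(1, 3))
    return SlideImage(
        pixels=np.clip(np.round(small), 0, 255).astype(np.uint8),
        stain_kind=img.stain_kind,
        magnification_level=MagnificationLevel.LOWRES,
        downscale_factor=factor,
        slide_id=img.slide_id,
    )


def _luma(rgb: np.ndarray) -> np.ndarray:
    return rgb.astype(np.float64) @ _LUMA


def prepare_threshold_channel(img: SlideImage, cfg: MaskingConfig | None = None) -> np.ndarray:
    """Build the single channel on which the tissue threshold operates.

    Near-black pixels (all three channels below the black-edge cutoff) are
    replaced by white first, so that black scanner borders do not drag the
    automatic threshold down.  PD-L1 slides are converted to grayscale
    (BT.601 luma); H&E slides use the eosin channel of an HED deconvolution
    (Ruifrok–Johnston stain matrix), min-max rescaled to [0, 255].

    Returns a float array in [0, 255].
    """
    cfg = cfg or MaskingConfig()
    rgb = np.asarray(img.pixels)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("prepare_threshold_channel requires an RGB raster")
    rgb = rgb.copy()
    black = np.all(rgb < cfg.black_edge_cutoff, axis=2)
    rgb[black] = 255

    if img.stain_kind == StainKind.PDL1:
        return _luma(rgb)
    # H&E: eosin is the discriminative stain (cytoplasm); deconvolve.
    hed = rgb2hed(rgb.astype(np.float64) / 255.0)
    eosin = hed[..., 1]
    lo, hi = eosin.min(), eosin.max()
    if hi > lo:
        eosin = (eosin - lo) / (hi - lo)
    else:
        eosin = np.zeros_like(eosin)
    # eosin *absorbance* is high on tissue; invert so tissue is dark like
    # the grayscale branch and a single polarity rule applies downstream
    return (1.0 - eosin) * 255.0


def compute_tissue_mask(channel: np.ndarray, cfg: MaskingConfig | None = None) -> tuple[np.ndarray, float]:
    """Threshold the prepared channel into a binary tissue mask.

    The applied threshold is ``min(otsu(channel), otsu_upper_bound)``;
    pixels strictly below it count as tissue (stained tissue is darker than
    the white glass background).  A constant channel has no Otsu threshold:
    an empty mask is returned with the upper bound recorded, with a warning.
    """
    cfg = cfg or MaskingConfig()
    channel = np.asarray(channel, dtype=np.float64)
    if channel.min() == channel.max():
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask",
                      stacklevel=2)
        return np.zeros(channel.shape, dtype=bool), float(cfg.otsu_upper_bound)
    otsu = float(threshold_otsu(np.clip(np.round(channel), 0, 255).astype(np.uint8)))
    threshold = min(otsu, float(cfg.otsu_upper_bound))
    return channel < threshold, threshold


def enumerate_tissue_patches(grid_mask: np.ndarray, cfg: MaskingConfig | None = None) -> list[tuple[int, int]]:
    """List working-resolution patch coordinates covered by tissue.

    The low-resolution mask is tiled into non-overlapping 32x32 tiles
    (partial border tiles are discarded).  Each tile splits into sixteen
    8x8 sub-patches; a sub-patch is "tissue" when it holds at least
    ``min_tissue_px_per_subpatch`` true pixels, and the tile qualifies when
    strictly more than ``min_coverage_fraction`` of its sub-patches are
    tissue.  Coordinates are returned as 0-based (row, col) multiples of
    512 at working resolution, in row-major order.
    """
    cfg = cfg or MaskingConfig()
    mask = np.asarray(grid_mask, dtype=bool)
    t, s = TILE_LOWRES, cfg.subpatch_px
    nrows, ncols = mask.shape[0] // t, mask.shape[1] // t
    if nrows == 0 or ncols == 0:
        return []
    sub = t // s
    m = mask[: nrows * t, : ncols * t].reshape(nrows, sub, s, ncols, sub, s)
    sub_counts = m.sum(axis=(2, 5))                     # (nrows, sub, ncols, sub)
    tissue_sub = sub_counts >= cfg.min_tissue_px_per_subpatch
    coverage = tissue_sub.sum(axis=(1, 3)) / (sub * sub)
    keep = coverage > cfg.min_coverage_fraction
    rows, cols = np.nonzero(keep)
    return [(int(r) * t * DOWNSCALE, int(c) * t * DOWNSCALE) for r, c in zip(rows, cols)]


def combine_overlap_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Elementwise AND of two tissue masks (paired-stain overlap)."""
    a, b = np.asarray(mask_a, dtype=bool), np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask dimensions differ: {a.shape} vs {b.shape}")
    return a & b


def sample_training_patches(locs: list[tuple[int, int]], cfg: MaskingConfig | None = None) -> list[tuple[int, int]]:
    """Cap a patch list at ``training_patch_cap`` by uniform sampling.

    Slides yielding more than the cap are subsampled without replacement
    (reproducible under ``cfg.rng_seed``); smaller lists pass through
    unchanged.  Sampled subsets preserve the original ordering.
    """
    cfg = cfg or MaskingConfig()
    if len(locs) <= cfg.training_patch_cap:
        return list(locs)
    rng = np.random.default_rng(cfg.rng_seed)
    idx = rng.choice(len(locs), size=cfg.training_patch_cap, replace=False)
    return [locs[i] for i in sorted(idx)]


def tissue_grid(img: SlideImage, cfg: MaskingConfig | None = None) -> TissueGrid:
    """Full tissue-detection pipeline for one working-resolution slide."""
    cfg = cfg or MaskingConfig()
    low = img if img.downscale_factor == DOWNSCALE else downscale_slide(img)
    channel = prepare_threshold_channel(low, cfg)
    mask, threshold = compute_tissue_mask(channel, cfg)
    locs = enumerate_tissue_patches(mask, cfg)
    return TissueGrid(mask=mask, threshold_used=threshold, patch_locations=locs)
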