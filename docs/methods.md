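# Methods

## Problem and pipeline

`peerce` estimates the PD-L1 tumor proportion score (TPS) of an
immunohistochemistry-stained slide by explicit cell counting, and supports
the clinical workflow in which an AI score is used as a second opinion
against pathologist estimates. The TPS is

    TPS = 100 · TC+ / (TC+ + TC−)

where TC+ and TC− are the numbers of PD-L1 positive and negative tumor
cells; other cells (OC — lymphocytes, plasma cells, macrophages, …) are
detected but never enter the ratio. A slide with no detected tumor cells
has an *undefined* TPS, reported as an explicit null: collapsing a failed
detection to "0% — PD-L1 negative" would be a silent clinical error.

The pipeline has four stages:

1. **Tissue masking.** The slide is block-averaged down by 16×, near-black
   scan-edge pixels (all channels < 20) are pushed to white, and a single
   thresholding channel is built — BT.601 grayscale for PD-L1/DAB slides,
   the (inverted, rescaled) eosin absorbance of a Ruifrok–Johnston HED
   deconvolution for H&E. The tissue threshold is Otsu's, capped at a
   fixed upper bound (default 220/255) because faint slides can otherwise
   drive Otsu so high that background is called tissue. Pixels strictly
   below the threshold are tissue. The low-resolution mask is walked in
   non-overlapping 32×32 tiles (one 512×512 working-resolution patch
   each); a tile splits into sixteen 8×8 sub-patches, a sub-patch is
   "tissue" at ≥ 5 tissue pixels, and the tile is kept when strictly more
   than 60% of sub-patches are tissue. Paired-stain workflows AND the two
   masks; training extraction caps a slide at 500 patches by seeded
   uniform subsampling.
2. **Tumor patch detection.** Each candidate patch goes through a 2-class
   per-pixel classifier; the patch's tumor score is the mean pixelwise
   softmax probability of the tumor class. Patches scoring > 0.6 are
   selected; if fewer than 10 qualify, the 10 best-scoring patches are
   taken instead (ties broken row-major), which is the deterministic
   equivalent of "lowering the threshold until 10 patches qualify".
3. **Cell detection and typing.** Nuclei are detected on the
   grayscale-inverted patch; when a hematoxylin-transform backend is
   configured the detector also runs on a hematoxylin-only re-rendering
   and the branch with strictly more cells wins (tie → original). Strong
   DAB staining resembles chromatin in grayscale, which is exactly the
   failure the fallback addresses. Each instance is typed by averaging a
   4-class (TC+, TC−, OC, background) per-pixel softmax over its mask,
   discarding the background entry, and taking the argmax with fixed
   tie priority TC+ > TC− > OC.
4. **Aggregation and concordance.** TC+/TC− counts are summed over all
   selected patches into the slide TPS; multi-slide patients default to
   the arithmetic mean of defined slide scores. Against pathologist
   tables, an assessment is flagged for re-evaluation when
   |AI − rater| > 10 percentage points (strictly); decision-level
   agreement binarizes both scores at a 20% cutoff (≥ 20 positive);
   per-rater Pearson correlations (Spearman optional) and their mean
   summarize continuous agreement; reassessment bookkeeping counts
   flagged/changed/unchanged assessments over patients × raters.

## Backends

The segmentation models are pluggable contracts, so heavier architectures
can be slotted in without touching the pipeline.

* **Pixel classifier (`PixelSoftmaxNet`).** Each pixel is described by its
  normalized color (fixed natural-image-corpus channel statistics) plus
  Gaussian-smoothed color context at σ = 2 and σ = 6 px; a one-hidden-layer
  network (24 units, ReLU) maps the 9 features to per-class raw scores.
  Training is AdamW (decoupled weight decay 0.01) with a cosine-annealed
  learning rate starting at 10⁻³, batches of 8 patches, and class-weighted
  cross-entropy with an ignore-label that contributes no loss or gradient.
  The cell-typing head weights background 0.0004 against 1 for the three
  cell classes — after masking unannotated cells, background pixels vastly
  outnumber annotated ones. The output layer is zero-initialized (training
  starts from a uniform softmax) and each patch batch is optimized in
  pixel minibatches of 2048 so that short runs still take enough AdamW
  steps. Flip augmentation (p = 0.5 per axis), affine jitter (translate
  ±10%, scale 0.9–1.1, shear ±5°) and color jitter
  (brightness/contrast/saturation ±0.2, hue ±0.05) apply in training only;
  normalization applies always. Full-scale defaults are 50 epochs (tumor)
  and 25 (cell typing).
* **Nucleus detection (`WatershedNucleusDetector`).** Grayscale inversion,
  Otsu foreground, small-speck removal, then a distance-transform
  watershed seeded at maxima spaced by ~0.45 of the nominal nucleus
  diameter (default 15 px). A test-time augmentation mode (best over the
  four axis flips) exists but defaults off for reproducibility.
* **Hematoxylin transform (`HedHemaTransform`).** HED deconvolution with
  eosin and DAB zeroed, reconstructed to RGB. It satisfies the same
  contract as a learned IHC→hematoxylin translator and is sufficient to
  exercise the dual-branch rule.
* **Oracle backends** emit ground truth through the production interfaces
  (one-hot score maps; ground-truth masks assigned to the patch containing
  each cell's centroid). They validate plumbing, never modeling.

## Training from sparse point annotations

Real annotation marks a cell's position and class but not its outline.
A marked point labels the detected instance mask containing it (disk of
radius 7 px if no instance), unannotated detected instances are
ignore-labeled (cells of unknown type must not train the background
class), and remaining pixels are background. Overlapping claims resolve to
the nearest annotation point; conflicting marks on one instance warn.

## Synthetic data: what it emulates, and what it does not

The generator renders mini-slides at working resolution with exact ground
truth: pale-pink elliptical tissue blobs on white glass (texture noise
σ = 6), tumor regions slightly more eosinophilic than stroma, blue-purple
elliptical nuclei (diameter ~15 px, ±15% axis jitter), smaller darker
hyperchromatic OC nuclei (0.6× diameter — non-tumor cells are typically
smaller than cancer cells), a DAB-brown membrane ring (width 3 px) plus a
faint brown nuclear tint on TC+ cells, per-cell stain jitter (σ = 5%
multiplicative), and an optional near-black scan-edge band. The brown
ring's grayscale intensity is deliberately close to nuclear chromatin so
the hema-fallback branch is genuinely exercised. Cell placement is
rejection sampling with minimum center spacing of one nucleus diameter.
Cohort-default conditions: 3072×3072 canvas, 3 blobs (semi-axes
500–900 px), tumor fraction 0.5, 400 cells of which 30% OC (close to the
OC share of the annotated clinical cohort), requested TPS realized exactly
by construction (TC+ count = round(TPS/100 · tumor cells)).

Two deliberate design couplings make ground truth recoverable by
construction: tumor cells are placed only inside full 512-px tiles whose
tumor fraction is ≥ 0.7 (every tumor cell therefore lies in a patch a
correct selection stage must select), and cells keep a margin of about one
patch diagonal quantization from region boundaries. Simulated pathologists
score clip(truth + bias + N(0, σ), 0, 100) with per-case or per-case-and-
rater bias rules.

The generator does **not** model: chromatin texture, nucleoli, touching
and overlapping nuclei beyond spacing jitter, cytoplasmic or immune-cell
PD-L1 staining, stain variability across labs, tissue folds, blur, or
misalignment between paired stains. Passing recovery tests therefore
demonstrates that the pipeline's logic is correct on cleanly separable
imagery — not that the toy backends would perform on clinical slides;
those require full-scale encoder-decoder models and real training data.

## Numerical choices and degenerate inputs

* Otsu on a constant channel is undefined: empty mask, threshold reported
  as the upper bound, with a warning.
* "More than 60%" coverage is strict (> , i.e. ≥ 10 of 16 sub-patches);
  "five or more" is inclusive; the 0.6 tumor threshold is strict; the
  10-pp discrepancy flag is strict; the 20% cutoff is inclusive (≥).
* Partial border tiles (mask not a multiple of 32) are discarded.
* Patch coordinates are 0-based (row, col) multiples of 512 at working
  resolution, row-major.
* Softmax is computed with max-subtraction; non-finite raw scores raise.
* Ties in per-cell argmax resolve TC+ > TC− > OC (first-maximum rule).
* Undefined TPS propagates as null through patient aggregation (mean of
  the defined slides; null only if all slides are undefined).
* Percentages are reported to 2 decimals, round-half-even.

## Experiment scales

The recovery experiments (`peerce.experiments`) use 10 held-out slides
spanning TPS 0–80% and, for the learned variant, 40 training patches from
4 slides (TPS 10/30/55/75) with 25 point-annotated cells per patch —
mirroring the real annotation density of ~20–30 cells per patch. Toy
training uses 12 epochs, learning rate 0.01, 3000 sampled pixels per
patch, and flip-only augmentation; the synthetic palette is cleanly
separable, so longer schedules change nothing. All randomness flows from a
single seed; training, generation and inference are deterministic given
it.

## Known limitations

* The default backends are CPU-scale stand-ins behind the spec'd
  contracts; no trained clinical weights ship with the package.
* Per-patch instance detection can double-count a cell straddling two
  selected patches (the oracle provider resolves this by centroid; the
  classical detector cannot). At realistic patch counts this perturbs both
  numerator and denominator and has negligible effect on the ratio.
* Slide I/O covers plain TIFF/PNG rasters; proprietary pyramidal scanner
  formats are out of scope.
* The concordance layer reports per-rater cutoff accuracies and their
  mean; it does not attempt to reproduce any particular averaging basis
  beyond that.
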