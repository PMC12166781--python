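"""Trainable per-pixel softmax classifier used by both segmentation stages.

The pipeline needs a pixel classifier twice: a 2-class tumor/non-tumor head
for patch scoring and a 4-class (TC+, TC-, OC, background) head for cell
typing.  Both are served by :class:`PixelSoftmaxNet`, a deliberately small
network that runs comfortably on a single CPU: each pixel is described by
its normalized color plus Gaussian-smoothed color context at two scales
(local texture / cellularity cues), and a one-hidden-layer network maps
that feature vector to per-class raw scores.  Training uses AdamW with a
cosine-annealed learning rate and a class-weighted cross-entropy that skips
ignore-labeled pixels, so sparse point annotations can be used directly.

The class satisfies the pixel-classifier backend contract: output spatial
dimensions equal input dimensions, and inference is deterministic for
fixed weights.  Heavier encoder-decoder architectures can be slotted in
behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, warp

__all__ = ["TrainConfig", "PixelSoftmaxNet", "softmax_channels"]

#: ignore-label value in per-pixel label maps (no loss contribution)
IGNORE_LABEL = 255

# channel statistics of the large natural-image corpus used for encoder
# pre-training; normalization applied at train and inference time alike
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class TrainConfig:
    """Hyperparameters of the segmentation trainer.

    Defaults follow the pipeline's full-scale settings (50 epochs for tumor
    detection, 25 for cell typing — pass ``epochs`` accordingly); toy runs
    scale ``epochs`` and ``pixels_per_patch`` down.
    """

    epochs: int = 50
    initial_lr: float = 1e-3
    weight_decay: float = 0.01        # AdamW decoupled weight decay
    batch_size: int = 8
    lr_schedule: str = "cosine"       # cosine annealing to ~0
    class_weights: tuple[float, ...] | None = None
    ignore_label: int = IGNORE_LABEL
    # augmentation (training only)
    flip_p: float = 0.5               # per axis
    affine: bool = True
    translate_frac: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    shear_deg: float = 5.0
    color_jitter: bool = True
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    # normalization (applied always)
    norm_mean: tuple[float, float, float] = IMAGENET_MEAN
    norm_std: tuple[float, float, float] = IMAGENET_STD
    # toy-scale knobs
    hidden_units: int = 24
    context_sigmas: tuple[float, ...] = (2.0, 6.0)
    pixels_per_patch: int = 4096      # SGD pixel subsample per patch per epoch
    pixel_batch: int = 2048           # pixels per optimizer step
    rng_seed: int = 0


def softmax_channels(raw: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw scores contain NaN or infinite values")
    z = raw - raw.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _normalize(rgb: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    x = np.asarray(rgb, dtype=np.float64) / 255.0
    return (x - np.asarray(cfg.norm_mean)) / np.asarray(cfg.norm_std)


def _features(rgb: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """Per-pixel feature stack: normalized RGB + Gaussian context at each sigma."""
    x = _normalize(rgb, cfg)
    feats = [x]
    for sigma in cfg.context_sigmas:
        feats.append(np.stack([gaussian_filter(x[..., c], sigma) for c in range(3)], axis=-1))
    return np.concatenate(feats, axis=-1)


def _augment(rgb: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    img = rgb
    lab = labels
    if rng.random() < cfg.flip_p:
        img, lab = img[::-1], lab[::-1]
    if rng.random() < cfg.flip_p:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if cfg.affine:
        h, w = lab.shape
        tform = AffineTransform(
            scale=rng.uniform(*cfg.scale_range),
            shear=np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg)),
            translation=(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w,
                         rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h),
        )
        img = warp(img.astype(np.float64) / 255.0, tform.inverse, order=1,
                   mode="constant", cval=1.0)  # pad with white glass
        img = np.clip(img * 255.0, 0, 255)
        lab = warp(lab.astype(np.float64), tform.inverse, order=0,
                   mode="constant", cval=float(cfg.ignore_label)).astype(labels.dtype)
    if cfg.color_jitter:
        x = np.clip(np.asarray(img, dtype=np.float64) / 255.0, 0, 1)
        x = np.clip(x * (1 + rng.uniform(-cfg.brightness, cfg.brightness)), 0, 1)
        x = np.clip((x - x.mean()) * (1 + rng.uniform(-cfg.contrast, cfg.contrast)) + x.mean(), 0, 1)
        hsv = rgb2hsv(x)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue, cfg.hue)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-cfg.saturation, cfg.saturation)), 0, 1)
        img = np.clip(hsv2rgb(hsv) * 255.0, 0, 255)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


class _AdamW:
    """AdamW on a flat list of parameter arrays (decoupled weight decay)."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


class PixelSoftmaxNet:
    """One-hidden-layer per-pixel classifier over color + context features.

    Parameters
    ----------
    n_classes : number of output classes (2 for tumor, 4 for cell typing).
    config : training hyperparameters; also fixes the feature extractor
        (normalization constants and context scales), which therefore
        applies identically at inference time.
    """

    def __init__(self, n_classes: int, config: TrainConfig | None = None):
        self.n_classes = int(n_classes)
        self.config = config or TrainConfig()
        self.n_features = 3 * (1 + len(self.config.context_sigmas))
        rng = np.random.default_rng(self.config.rng_seed)
        h = self.config.hidden_units
        self.W1 = rng.normal(0, np.sqrt(2.0 / self.n_features), (self.n_features, h))
        self.b1 = np.zeros(h)
        # zero-initialized head: training starts from a uniform softmax
        self.W2 = np.zeros((h, self.n_classes))
        self.b2 = np.zeros(self.n_classes)
        self.loss_history: list[float] = []

    # -- inference -----------------------------------------------------

    def _raw_from_features(self, feats: np.ndarray) -> np.ndarray:
        hidden = np.maximum(feats @ self.W1 + self.b1, 0.0)
        return hidden @ self.W2 + self.b2

    def predict_raw(self, patch: np.ndarray, *, location=None) -> np.ndarray:
        """Per-pixel raw class scores, shape (H, W, C)."""
        patch = np.asarray(patch)
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError("expected an RGB patch (H, W, 3)")
        return self._raw_from_features(_features(patch, self.config))

    def predict_proba(self, patch: np.ndarray, *, location=None) -> np.ndarray:
        """Per-pixel softmax probabilities, shape (H, W, C)."""
        return softmax_channels(self.predict_raw(patch), axis=-1)

    # -- training ------------------------------------------------------

    def fit(self, patches: list[np.ndarray], label_maps: list[np.ndarray],
            config: TrainConfig | None = None) -> "PixelSoftmaxNet":
        """Train on RGB patches with per-pixel integer labels.

        Pixels carrying ``config.ignore_label`` contribute zero loss and
        zero gradient.  ``config.class_weights`` reweights the per-pixel
        cross-entropy (used to downweight the dominant background class).
        """
        cfg = config or self.config
        self.config = cfg
        if not patches:
            raise ValueError("no training patches given")
        if not any((np.asarray(l) != cfg.ignore_label).any() for l in label_maps):
            raise ValueError("no annotated (non-ignored) pixels in the training set")
        weights = np.ones(self.n_classes) if cfg.class_weights is None \
            else np.asarray(cfg.class_weights, dtype=np.float64)
        if weights.shape != (self.n_classes,):
            raise ValueError("class_weights length must equal n_classes")

        rng = np.random.default_rng(cfg.rng_seed)
        params = [self.W1, self.b1, self.W2, self.b2]
        opt = _AdamW(params, cfg.initial_lr, cfg.weight_decay)
        n = len(patches)
        self.loss_history = []

        # features are flip-equivariant, so with only flip augmentation the
        # (expensive) feature maps can be computed once and flipped per epoch
        cache_feats = not cfg.affine and not cfg.color_jitter
        feats_cache = [_features(np.asarray(p), cfg) for p in patches] if cache_feats else None

        for epoch in range(cfg.epochs):
            if cfg.lr_schedule == "cosine":
                opt.lr = cfg.initial_lr * 0.5 * (1 + np.cos(np.pi * epoch / max(cfg.epochs, 1)))
            order = rng.permutation(n)
            epoch_loss, epoch_px = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                xs, ys, ws = [], [], []
                for i in order[start:start + cfg.batch_size]:
                    if cache_feats:
                        feats, lab = feats_cache[i], np.asarray(label_maps[i])
                        if rng.random() < cfg.flip_p:
                            feats, lab = feats[::-1], lab[::-1]
                        if rng.random() < cfg.flip_p:
                            feats, lab = feats[:, ::-1], lab[:, ::-1]
                    else:
                        img, lab = _augment(np.asarray(patches[i]),
                                            np.asarray(label_maps[i]), cfg, rng)
                        feats = _features(img, cfg)
                    feats = feats.reshape(-1, self.n_features)
                    lab = lab.reshape(-1)
                    valid = np.nonzero(lab != cfg.ignore_label)[0]
                    if valid.size == 0:
                        continue
                    if valid.size > cfg.pixels_per_patch:
                        valid = rng.choice(valid, size=cfg.pixels_per_patch, replace=False)
                    xs.append(feats[valid])
                    ys.append(lab[valid])
                    ws.append(weights[lab[valid]])
                if not xs:
                    continue
                x = np.concatenate(xs)
                y = np.concatenate(ys).astype(np.intp)
                w = np.concatenate(ws)
                perm = rng.permutation(len(y))
                for lo in range(0, len(y), cfg.pixel_batch):
                    sel = perm[lo:lo + cfg.pixel_batch]
                    loss = self._step(x[sel], y[sel], w[sel], opt)
                    epoch_loss += loss * len(sel)
                    epoch_px += len(sel)
            self.loss_history.append(epoch_loss / max(epoch_px, 1))
        return self

    def _step(self, x: np.ndarray, y: np.ndarray, w: np.ndarray, opt: _AdamW) -> float:
        hidden_pre = x @ self.W1 + self.b1
        hidden = np.maximum(hidden_pre, 0.0)
        raw = hidden @ self.W2 + self.b2
        probs = softmax_channels(raw, axis=-1)
        n = len(y)
        wsum = w.sum()
        loss = float(-(w * np.log(probs[np.arange(n), y] + 1e-12)).sum() / wsum)

        draw = probs.copy()
        draw[np.arange(n), y] -= 1.0
        draw *= (w / wsum)[:, None]
        gW2 = hidden.T @ draw
        gb2 = draw.sum(axis=0)
        dhidden = draw @ self.W2.T
        dhidden[hidden_pre <= 0] = 0.0
        gW1 = x.T @ dhidden
        gb1 = dhidden.sum(axis=0)
        opt.step([gW1, gb1, gW2, gb2])
        return loss

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
                 n_classes=self.n_classes)

    @classmethod
    def load(cls, path, config: TrainConfig | None = None) -> "PixelSoftmaxNet":
        data = np.load(path)
        net = cls(int(data["n_classes"]), config)
        net.W1, net.b1 = data["W1"], data["b1"]
        net.W2, net.b2 = data["W2"], data["b2"]
        return net
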