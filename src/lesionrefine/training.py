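"""Training for both stages: box-stage SGD with the poly schedule, hard-example
mining, and click-stage training with per-pass interaction simulation.

The box stage trains end-to-end (encoder + context + head) on jittered-box
crops with pixel-wise binary cross-entropy.  The click stage then trains on
the *hard* subset — objects the coarse stage segments at IoU below a
threshold (default 0.9) — with the coarse network frozen: every pass
re-simulates user clicks from the current coarse mistakes, encodes them as
guidance, and minimizes the cross-entropy of the *fused* logits
``F = W * C + B``, so the refinement head learns corrections exactly where
clicks grant it weight.

Both stages use momentum SGD under the poly learning-rate policy
``lr = base_lr * (1 - iter / max_iter) ** power``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .geometry import SurroundingBox, binarize, crop
from .guidance import GuidanceConfig, encode_clicks, weight_map
from .interaction import allocate_clicks, error_sets, jitter_box, sample_clicks, tight_bbox
from .metrics import mask_iou
from .networks import ModelConfig, TwoStageModel

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "poly_lr",
    "train_sbox",
    "mine_hard_examples",
    "train_click",
    "sbox_iou",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and simulation settings shared by both training stages."""

    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 8
    epochs: int = 50
    poly_power: float = 0.9
    click_lr: float = 0.1
    hard_iou_threshold: float = 0.9
    max_jitter: int = 30          # box-edge jitter in image pixels
    clicks_per_round: int = 3     # simulated clicks per object per click-stage pass
    resample_clicks_each_pass: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.base_lr <= 0 or self.click_lr <= 0:
            raise ValueError("learning rates must be > 0")
        if not 0 <= self.hard_iou_threshold <= 1:
            raise ValueError("hard_iou_threshold must be in [0, 1]")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


@dataclass
class TrainHistory:
    epoch_loss: list = field(default_factory=list)
    val_iou: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)


def poly_lr(base_lr: float, it: int, max_iter: int, power: float) -> float:
    """Poly policy: ``base_lr * (1 - iter/max_iter) ** power``."""
    if max_iter <= 0:
        raise ValueError("max_iter must be > 0")
    if not 0 <= it <= max_iter:
        raise ValueError(f"iter {it} outside [0, {max_iter}]")
    return base_lr * (1.0 - it / max_iter) ** power


# ---------------------------------------------------------------------------
# crop plumbing shared by training and inference
# ---------------------------------------------------------------------------

def resize_image(img: np.ndarray, hw: tuple) -> np.ndarray:
    return _sk_resize(img.astype(float), hw, order=1, preserve_range=True,
                      anti_aliasing=False)


def resize_mask(mask: np.ndarray, hw: tuple) -> np.ndarray:
    return _sk_resize(mask, hw, order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.uint8)


def resize_logits(logits: np.ndarray, hw: tuple) -> np.ndarray:
    return _sk_resize(logits.astype(float), hw, order=1, preserve_range=True,
                      anti_aliasing=False)


def _as_pairs(dataset):
    pairs = []
    for s in dataset:
        if hasattr(s, "image"):
            pairs.append((s.image, s.mask))
        else:
            pairs.append((s[0], s[1]))
    if not pairs:
        raise ValueError("dataset is empty")
    return pairs


def _make_batch(pairs, idx, crop_size, max_jitter, rng):
    """Jitter boxes, crop, and resize a mini-batch to the network resolution."""
    imgs, masks = [], []
    for i in idx:
        img, mask = pairs[i]
        box = tight_bbox(mask)
        if max_jitter > 0:
            box = jitter_box(box, max_jitter, mask.shape, rng)
        imgs.append(resize_image(crop(img, box), (crop_size, crop_size)))
        masks.append(resize_mask(crop(mask, box), (crop_size, crop_size)))
    return np.stack(imgs), np.stack(masks)


def sbox_iou(model: TwoStageModel, image: np.ndarray, mask: np.ndarray) -> float:
    """Coarse-stage IoU of one sample under its tight (unjittered) box,
    evaluated at the crop's native resolution."""
    box = tight_bbox(mask)
    cs = model.cfg.crop_size
    x = model.preprocess(resize_image(crop(image, box), (cs, cs))[None])
    b, _ = model.sbox_forward(x)
    native = resize_logits(b[0, 0], (box.height, box.width))
    return mask_iou(binarize(native), crop(mask, box))


# ---------------------------------------------------------------------------
# stage 1: coarse (box-guided) training
# ---------------------------------------------------------------------------

def train_sbox(dataset, mc: ModelConfig, tc: TrainConfig, val_dataset=None):
    """Train encoder + context + box head; returns (model, history).

    Per sample and epoch the ground-truth tight box is re-jittered (uniform
    integer offset per edge, up to ``tc.max_jitter`` pixels), the crop is
    resized to the network resolution, and pixel-wise binary cross-entropy on
    the coarse logits drives momentum SGD under the poly schedule.
    """
    pairs = _as_pairs(dataset)
    if any(m.sum() == 0 for _, m in pairs):
        raise ValueError("all training masks must be non-empty")
    model = TwoStageModel(mc)
    hist = _fit_sbox(model, pairs, tc, val_dataset)
    return model, hist


def _fit_sbox(model, pairs, tc, val_dataset):
    hist = TrainHistory()
    if tc.epochs == 0:
        return hist
    rng = np.random.default_rng(tc.seed)
    opt = nn.SGDMomentum(model.params_sbox(), tc.momentum, tc.weight_decay)
    n = len(pairs)
    n_batches = math.ceil(n / tc.batch_size)
    max_iter = tc.epochs * n_batches
    cs = model.cfg.crop_size
    it = 0
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, tc.batch_size):
            idx = order[b0 : b0 + tc.batch_size]
            imgs, masks = _make_batch(pairs, idx, cs, tc.max_jitter, rng)
            x = model.preprocess(imgs)
            b, _ = model.sbox_forward(x)
            loss, db = nn.bce_with_logits(b, masks[:, None])
            opt.zero_grad()
            model.sbox_backward(db.astype(b.dtype))
            lr = poly_lr(tc.base_lr, it, max_iter, tc.poly_power)
            opt.step(lr)
            hist.lr_trace.append(lr)
            it += 1
            losses.append(loss)
        hist.epoch_loss.append(float(np.mean(losses)))
        hist.val_iou.append(
            float(np.mean([sbox_iou(model, im, mk) for im, mk in _as_pairs(val_dataset)]))
            if val_dataset else float("nan")
        )
    return hist


# ---------------------------------------------------------------------------
# hard-example mining
# ---------------------------------------------------------------------------

def mine_hard_examples(model: TwoStageModel, dataset, threshold: float | None = None):
    """Samples whose coarse IoU (tight box, no jitter) falls below ``threshold``."""
    thr = 0.9 if threshold is None else threshold
    return [s for s in dataset
            if sbox_iou(model, *(s.image, s.mask) if hasattr(s, "image") else s) < thr]


# ---------------------------------------------------------------------------
# stage 2: click-guided residual training (coarse stage frozen)
# ---------------------------------------------------------------------------

def train_click(model: TwoStageModel, hard_dataset, tc: TrainConfig,
                guidance: GuidanceConfig | None = None):
    """Train only the click head on the hard subset; returns TrainHistory.

    Each pass: frozen coarse forward -> current error sets -> simulated
    clicks (budget split between polarities proportionally to the error
    areas) -> guidance + weight maps -> fused logits -> cross-entropy.
    Gradients flow only through ``W * C``; the coarse parameters are never
    touched.
    """
    pairs = _as_pairs(hard_dataset)
    hist = TrainHistory()
    if tc.epochs == 0:
        return hist
    cs = model.cfg.crop_size
    g = (guidance or GuidanceConfig().scaled_for(cs))
    rng = np.random.default_rng(tc.seed)
    opt = nn.SGDMomentum(model.params_click(), tc.momentum, tc.weight_decay)
    n = len(pairs)
    n_batches = math.ceil(n / tc.batch_size)
    max_iter = tc.epochs * n_batches
    it = 0
    fixed_clicks = {}  # only used when clicks are sampled once per object
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, tc.batch_size):
            idx = order[b0 : b0 + tc.batch_size]
            imgs, masks = _make_batch(pairs, idx, cs, tc.max_jitter, rng)
            x = model.preprocess(imgs)
            b, ctx = model.sbox_forward(x)
            pred = (b[:, 0] > 0).astype(np.uint8)
            gmaps, wmaps = [], []
            for k, i in enumerate(idx):
                key = int(i)
                if not tc.resample_clicks_each_pass and key in fixed_clicks:
                    clicks = fixed_clicks[key]
                else:
                    fn, fp = error_sets(pred[k], masks[k])
                    n_pos, n_neg = allocate_clicks(tc.clicks_per_round, len(fn), len(fp))
                    clicks = sample_clicks(pred[k], masks[k], n_pos, n_neg, rng)
                    fixed_clicks[key] = clicks
                gmaps.append(encode_clicks(clicks, g.radius, (cs, cs)).stacked())
                wmaps.append(weight_map(clicks, g.weight_radius, (cs, cs)).w)
            gbatch = np.stack(gmaps)
            w = np.stack(wmaps)[:, None]
            c = model.click_forward(ctx, gbatch)
            f = w * c + b
            loss, df = nn.bce_with_logits(f, masks[:, None])
            opt.zero_grad()
            model.click_backward((df * w).astype(c.dtype))
            lr = poly_lr(tc.click_lr, it, max_iter, tc.poly_power)
            opt.step(lr)
            hist.lr_trace.append(lr)
            it += 1
            losses.append(loss)
        hist.epoch_loss.append(float(np.mean(losses)))
        hist.val_iou.append(float("nan"))
    return hist


def desk_scale_config(crop_size: int = 96, context: str = "aspp", seed: int = 0) -> tuple:
    """A (ModelConfig, TrainConfig) pair sized for CPU experiments on 96 px
    synthetic images: <100k parameters, box jitter scaled to the image scale."""
    mc = ModelConfig(crop_size=crop_size, context=context, seed=seed)
    # 30 px of jitter on ~512 px dermoscopy frames ~ 6 px at a 96 px frame
    tc = TrainConfig(max_jitter=max(1, round(30 * crop_size / 512)), seed=seed)
    return mc, tc


def with_overrides(tc: TrainConfig, **kw) -> TrainConfig:
    return replace(tc, **kw)
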