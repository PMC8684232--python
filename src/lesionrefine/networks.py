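"""Segmentation networks: shared encoder, box-stage head, click-stage head.

The architecture mirrors the coarse-to-fine contract of the pipeline:

* a convolutional **encoder** produces features at two abstraction levels —
  shallow/high-resolution at stride 4 and deep/context-rich at stride 16;
* a pluggable **global-context extractor** (ASPP, PSP, or a naive 3x3
  convolution) enriches the deep features while preserving their spatial size;
* the **box-stage head** reduces the shallow channels with a 1x1 convolution,
  bilinearly upsamples the context features x4 to the shallow grid,
  concatenates, refines with a 3x3 convolution, projects to a single logit
  channel and upsamples x4 back to crop resolution (coarse logits ``B``);
* the **click-stage head** reduces the context channels with a 1x1
  convolution, concatenates the two Gaussian guidance channels (downsampled
  to the deep grid), and decodes to crop-resolution refinement logits ``C``.
  It consumes the *cached* context features of the box stage, so refinement
  never needs a second encoder pass.

The default configuration is a desk-scale model (tens of thousands of
parameters) trainable on one CPU; channel widths, crop size and the context
variant are all configurable, and the two-level feature contract (strides
4/16) is the seam through which a larger pretrained backbone could be swapped
in.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .guidance import GuidanceMaps

__all__ = ["ModelConfig", "TwoStageModel", "CONTEXT_VARIANTS"]

CONTEXT_VARIANTS = ("aspp", "psp", "naive")


@dataclass(frozen=True)
class ModelConfig:
    crop_size: int = 96
    widths: tuple = (8, 16, 24, 32)  # encoder channels at strides 1, 4, 8, 16
    ctx_channels: int = 32
    c_low_reduced: int = 8
    c_high_reduced: int = 16
    context: str = "aspp"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.crop_size % 16 != 0:
            raise ValueError("crop_size must be divisible by 16")
        if self.context not in CONTEXT_VARIANTS:
            raise ValueError(f"unknown context variant {self.context!r}")
        if any(w < 1 for w in self.widths):
            raise ValueError("channel widths must be >= 1")

    @property
    def low_hw(self) -> tuple:
        return (self.crop_size // 4, self.crop_size // 4)

    @property
    def high_hw(self) -> tuple:
        return (self.crop_size // 16, self.crop_size // 16)


class Encoder:
    """Five 3x3 convolutions; strided ones halve resolution.  Emits features
    at stride 4 (shallow) and stride 16 (deep)."""

    def __init__(self, rng, cfg: ModelConfig, dtype):
        c1, c2, c3, c4 = cfg.widths
        conv = lambda cin, cout, s: nn.Conv2d(rng, cin, cout, k=3, stride=s, dtype=dtype)
        self.stem = nn.Sequential(conv(3, c1, 1), nn.ReLU(), conv(c1, c2, 2), nn.ReLU(),
                                  conv(c2, c2, 2), nn.ReLU())          # -> stride 4
        self.deep = nn.Sequential(conv(c2, c3, 2), nn.ReLU(), conv(c3, c4, 2), nn.ReLU())

    def params(self):
        return self.stem.params() + self.deep.params()

    def forward(self, x):
        low = self.stem.forward(x)
        high = self.deep.forward(low)
        return low, high

    def backward(self, dlow, dhigh):
        d = self.deep.backward(dhigh)
        if dlow is not None:
            d = d + dlow
        # first conv's input gradient is never needed
        layers = self.stem.layers
        for l in layers[:0:-1]:
            d = l.backward(d)
        layers[0].backward(d, need_input_grad=False)


class _Concat:
    """Channel concatenation with remembered split points for backward."""

    def forward(self, parts):
        self.splits = np.cumsum([p.shape[1] for p in parts])[:-1]
        return np.concatenate(parts, axis=1)

    def backward(self, dy):
        return np.split(dy, self.splits, axis=1)


class ASPPContext:
    """Parallel branches: 1x1, dilated 3x3 (rates 1 and 2), and a global-pooled
    branch; concatenated and 1x1-projected."""

    def __init__(self, rng, cin, cout, hw, dtype):
        cb = max(cout // 2, 4)
        self.b0 = nn.Sequential(nn.Conv2d(rng, cin, cb, k=1, dtype=dtype), nn.ReLU())
        self.b1 = nn.Sequential(nn.Conv2d(rng, cin, cb, k=3, dilation=1, dtype=dtype), nn.ReLU())
        self.b2 = nn.Sequential(nn.Conv2d(rng, cin, cb, k=3, dilation=2, dtype=dtype), nn.ReLU())
        self.pool = nn.GlobalAvgPool(hw)
        self.b3 = nn.Sequential(nn.Conv2d(rng, cin, cb, k=1, dtype=dtype), nn.ReLU())
        self.unpool = nn.BilinearResize((1, 1), hw)
        self.cat = _Concat()
        self.proj = nn.Sequential(nn.Conv2d(rng, 4 * cb, cout, k=1, dtype=dtype), nn.ReLU())

    def params(self):
        return (self.b0.params() + self.b1.params() + self.b2.params()
                + self.b3.params() + self.proj.params())

    def forward(self, x):
        parts = [
            self.b0.forward(x),
            self.b1.forward(x),
            self.b2.forward(x),
            self.unpool.forward(self.b3.forward(self.pool.forward(x))),
        ]
        return self.proj.forward(self.cat.forward(parts))

    def backward(self, dy):
        d0, d1, d2, d3 = self.cat.backward(self.proj.backward(dy))
        dx = self.b0.backward(d0)
        dx += self.b1.backward(d1)
        dx += self.b2.backward(d2)
        dx += self.pool.backward(self.b3.backward(self.unpool.backward(d3)))
        return dx


class PSPContext:
    """Pyramid pooling at grid sizes {1, 2, 3, 6}, 1x1-projected per level,
    upsampled back and concatenated with the input, then 1x1-projected."""

    GRIDS = (1, 2, 3, 6)

    def __init__(self, rng, cin, cout, hw, dtype):
        cb = max(cout // 4, 2)
        self.levels = []
        for g in self.GRIDS:
            g = (min(g, hw[0]), min(g, hw[1]))
            self.levels.append(
                (
                    nn.AdaptiveAvgPool(hw, g),
                    nn.Sequential(nn.Conv2d(rng, cin, cb, k=1, dtype=dtype), nn.ReLU()),
                    nn.BilinearResize(g, hw),
                )
            )
        self.cat = _Concat()
        self.proj = nn.Sequential(
            nn.Conv2d(rng, cin + cb * len(self.GRIDS), cout, k=1, dtype=dtype), nn.ReLU()
        )

    def params(self):
        return [p for _, conv, _ in self.levels for p in conv.params()] + self.proj.params()

    def forward(self, x):
        parts = [x]
        for pool, conv, up in self.levels:
            parts.append(up.forward(conv.forward(pool.forward(x))))
        return self.proj.forward(self.cat.forward(parts))

    def backward(self, dy):
        dparts = self.cat.backward(self.proj.backward(dy))
        dx = dparts[0].copy()
        for (pool, conv, up), dp in zip(self.levels, dparts[1:]):
            dx += pool.backward(conv.backward(up.backward(dp)))
        return dx


class NaiveContext:
    """A single 3x3 convolution — the no-global-context baseline."""

    def __init__(self, rng, cin, cout, hw, dtype):
        self.net = nn.Sequential(nn.Conv2d(rng, cin, cout, k=3, dtype=dtype), nn.ReLU())

    def params(self):
        return self.net.params()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


_CONTEXT_CLASSES = {"aspp": ASPPContext, "psp": PSPContext, "naive": NaiveContext}


class SBoxHead:
    def __init__(self, rng, cfg: ModelConfig, dtype):
        c_low = cfg.widths[1]
        self.reduce_low = nn.Sequential(
            nn.Conv2d(rng, c_low, cfg.c_low_reduced, k=1, dtype=dtype), nn.ReLU()
        )
        self.up_ctx = nn.BilinearResize(cfg.high_hw, cfg.low_hw)
        self.cat = _Concat()
        cmid = cfg.ctx_channels
        self.refine = nn.Sequential(
            nn.Conv2d(rng, cfg.c_low_reduced + cfg.ctx_channels, cmid, k=3, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(rng, cmid, 1, k=1, dtype=dtype),
        )
        self.up_out = nn.BilinearResize(cfg.low_hw, (cfg.crop_size, cfg.crop_size))

    def params(self):
        return self.reduce_low.params() + self.refine.params()

    def forward(self, low, ctx):
        parts = [self.reduce_low.forward(low), self.up_ctx.forward(ctx)]
        return self.up_out.forward(self.refine.forward(self.cat.forward(parts)))

    def backward(self, db):
        dlowr, dctxu = self.cat.backward(self.refine.backward(self.up_out.backward(db)))
        return self.reduce_low.backward(dlowr), self.up_ctx.backward(dctxu)


class ClickHead:
    def __init__(self, rng, cfg: ModelConfig, dtype):
        self.reduce_ctx = nn.Sequential(
            nn.Conv2d(rng, cfg.ctx_channels, cfg.c_high_reduced, k=1, dtype=dtype), nn.ReLU()
        )
        self.down_guidance = nn.BilinearResize((cfg.crop_size, cfg.crop_size), cfg.high_hw)
        self.cat = _Concat()
        cmid = cfg.ctx_channels
        self.decode = nn.Sequential(
            nn.Conv2d(rng, cfg.c_high_reduced + 2, cmid, k=3, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(rng, cmid, cmid, k=3, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(rng, cmid, 1, k=1, dtype=dtype),
        )
        self.up_out = nn.BilinearResize(cfg.high_hw, (cfg.crop_size, cfg.crop_size))

    def params(self):
        return self.reduce_ctx.params() + self.decode.params()

    def forward(self, ctx, guidance):
        """guidance: (N, 2, crop, crop) stacked positive/negative channels."""
        g = self.down_guidance.forward(guidance.astype(ctx.dtype))
        x = self.cat.forward([self.reduce_ctx.forward(ctx), g])
        return self.up_out.forward(self.decode.forward(x))

    def backward(self, dc):
        dx = self.decode.backward(self.up_out.backward(dc))
        dctxr, _ = self.cat.backward(dx)
        # gradient into the (frozen) context features is not needed; stop at
        # the reduction conv after collecting its parameter gradients
        d = self.reduce_ctx.layers[1].backward(dctxr)
        self.reduce_ctx.layers[0].backward(d, need_input_grad=False)


class TwoStageModel:
    """Encoder + context extractor + box-stage head + click-stage head.

    ``sbox_forward`` caches the context features so that any number of
    refinement passes reuse them without touching the encoder again
    (``n_encoder_calls`` counts actual encoder passes).
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(rng, cfg, dtype)
        self.context = _CONTEXT_CLASSES[cfg.context](
            rng, cfg.widths[3], cfg.ctx_channels, cfg.high_hw, dtype
        )
        self.sbox_head = SBoxHead(rng, cfg, dtype)
        self.click_head = ClickHead(rng, cfg, dtype)
        self.n_encoder_calls = 0

    # ---- parameter groups -------------------------------------------------
    def params_sbox(self):
        return self.encoder.params() + self.context.params() + self.sbox_head.params()

    def params_click(self):
        return self.click_head.params()

    def param_count(self) -> int:
        return sum(p.value.size for p in self.params_sbox() + self.params_click())

    # ---- input plumbing ---------------------------------------------------
    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> normalized (N, 3, H, W) in [-1, 1]."""
        x = np.asarray(images, dtype=np.dtype(self.cfg.dtype))
        if x.ndim == 3:
            x = x[None]
        x = x.transpose(0, 3, 1, 2) / 127.5 - 1.0
        return x.astype(np.dtype(self.cfg.dtype))

    # ---- forward / backward ----------------------------------------------
    def sbox_forward(self, x: np.ndarray):
        """Return coarse logits B (N, 1, H, W) and cached context features."""
        n, c, h, w = x.shape
        if (h, w) != (self.cfg.crop_size, self.cfg.crop_size) or c != 3:
            raise ValueError(f"expected (N, 3, {self.cfg.crop_size}, {self.cfg.crop_size}), got {x.shape}")
        self.n_encoder_calls += 1
        low, high = self.encoder.forward(x)
        ctx = self.context.forward(high)
        b = self.sbox_head.forward(low, ctx)
        return b, ctx

    def sbox_backward(self, db: np.ndarray) -> None:
        dlow, dctx = self.sbox_head.backward(db)
        dhigh = self.context.backward(dctx)
        self.encoder.backward(dlow, dhigh)

    def click_forward(self, ctx: np.ndarray, guidance: np.ndarray) -> np.ndarray:
        """Refinement logits C from cached context features and guidance channels."""
        return self.click_head.forward(ctx, guidance)

    def click_backward(self, dc: np.ndarray) -> None:
        self.click_head.backward(dc)

    def guidance_batch(self, maps: list) -> np.ndarray:
        """Stack per-sample :class:`GuidanceMaps` into an (N, 2, H, W) array."""
        return np.stack([m.stacked() if isinstance(m, GuidanceMaps) else m for m in maps])

    # ---- persistence ------------------------------------------------------
    def state_arrays(self) -> list:
        return [p.value for p in self.params_sbox() + self.params_click()]

    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        cfg = dict(asdict(self.cfg))
        cfg["widths"] = list(cfg["widths"])
        np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TwoStageModel":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            cfg_dict["widths"] = tuple(cfg_dict["widths"])
            model = cls(ModelConfig(**cfg_dict))
            params = model.params_sbox() + model.params_click()
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.value.shape:
                    raise ValueError("checkpoint incompatible with config")
                p.value[...] = arr
        return model
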