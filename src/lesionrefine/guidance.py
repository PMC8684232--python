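"""Gaussian click encodings, the click weight map, and residual fusion.

A click at pixel (i, j) influences pixel (m, n) through the Gaussian kernel

    exp(-4 * ((m - i)^2 + (n - j)^2) / R^2)

where the radius ``R`` (pixels) controls the area of influence: the kernel is
1 at the click and decays to exp(-1) at Euclidean distance R/2.

Three maps are built from a click set:

* ``G1`` — per-pixel *maximum* of the kernels of the positive clicks;
* ``G2`` — the same for negative clicks;
* ``W``  — polarity-blind per-pixel *sum* of kernels at a much larger radius
  ``R_w``, which localizes where the refinement stage may alter the coarse
  result.

The two stages' outputs are combined by the residual fusion rule

    F = W * C + B        (elementwise)

with ``B`` the coarse (box-stage) logits and ``C`` the refinement logits.
Wherever no click exerts weight (W = 0) the fused result is exactly the
coarse result, so an empty click set is a strict no-op.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interaction import ClickSet

__all__ = ["GuidanceMaps", "WeightMap", "gaussian_guidance", "encode_clicks", "weight_map", "fuse"]

# Defaults are calibrated to a 256 x 256 crop; scale linearly for other crop
# sizes (see GuidanceConfig.scaled_for).
DEFAULT_RADIUS = 40.0
DEFAULT_WEIGHT_RADIUS_FACTOR = 3.0


@dataclass(frozen=True)
class GuidanceConfig:
    """Click-encoding radii in pixels at the network's crop resolution."""

    radius: float = DEFAULT_RADIUS
    weight_radius: float = DEFAULT_RADIUS * DEFAULT_WEIGHT_RADIUS_FACTOR
    reference_crop: int = 256

    def scaled_for(self, crop_size: int) -> "GuidanceConfig":
        s = crop_size / self.reference_crop
        return GuidanceConfig(self.radius * s, self.weight_radius * s, crop_size)


@dataclass(frozen=True)
class GuidanceMaps:
    g1: np.ndarray
    g2: np.ndarray
    radius: float

    def stacked(self) -> np.ndarray:
        """(2, H, W) array: channel 0 = positive guidance, channel 1 = negative."""
        return np.stack([self.g1, self.g2])


@dataclass(frozen=True)
class WeightMap:
    w: np.ndarray
    radius: float


def _kernel_grid(points, radius: float, shape: tuple) -> np.ndarray:
    """(K, H, W) stack of per-click Gaussian kernels."""
    h, w = shape
    rows = np.arange(h, dtype=float)[None, :, None]
    cols = np.arange(w, dtype=float)[None, None, :]
    pi = np.array([p[0] for p in points], dtype=float)[:, None, None]
    pj = np.array([p[1] for p in points], dtype=float)[:, None, None]
    d2 = (rows - pi) ** 2 + (cols - pj) ** 2
    return np.exp(-4.0 * d2 / radius**2)


def _check(radius: float, points, shape: tuple) -> None:
    if radius <= 0:
        raise ValueError("radius must be > 0")
    h, w = shape
    for r, c in points:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"click ({r}, {c}) outside shape {shape}")


def gaussian_guidance(clicks, radius: float, shape: tuple) -> np.ndarray:
    """Max-composed Gaussian click encoding; all-zero for an empty click list."""
    points = [(c.row, c.col) if hasattr(c, "row") else (c[0], c[1]) for c in clicks]
    _check(radius, points, shape)
    if not points:
        return np.zeros(shape, dtype=float)
    return _kernel_grid(points, radius, shape).max(axis=0)


def encode_clicks(cs: ClickSet, radius: float, shape: tuple) -> GuidanceMaps:
    """Encode positive and negative clicks into the two guidance channels."""
    return GuidanceMaps(
        g1=gaussian_guidance(cs.positives, radius, shape),
        g2=gaussian_guidance(cs.negatives, radius, shape),
        radius=radius,
    )


def weight_map(cs: ClickSet, weight_radius: float, shape: tuple) -> WeightMap:
    """Polarity-blind sum of click Gaussians at the (larger) weight radius.

    The sum is deliberately not clamped or normalized: repeated clicks in one
    area raise the weight there, and the refinement stage's training absorbs
    the scale.
    """
    points = [(c.row, c.col) for c in list(cs.positives) + list(cs.negatives)]
    _check(weight_radius, points, shape)
    if not points:
        return WeightMap(np.zeros(shape, dtype=float), weight_radius)
    return WeightMap(_kernel_grid(points, weight_radius, shape).sum(axis=0), weight_radius)


def fuse(b: np.ndarray, c: np.ndarray, w) -> np.ndarray:
    """Residual fusion ``F = W * C + B`` in the logit domain, elementwise."""
    wv = w.w if isinstance(w, WeightMap) else np.asarray(w)
    b = np.asarray(b)
    c = np.asarray(c)
    if not (b.shape == c.shape == wv.shape):
        raise ValueError(f"shape mismatch: B {b.shape}, C {c.shape}, W {wv.shape}")
    return wv * c + b
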