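"""Raster geometry primitives: binary masks, surrounding boxes, crop/paste.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based;
* boxes are half-open, ``[top, bottom) x [left, right)``;
* binary masks are ``uint8`` arrays whose elements are exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurroundingBox", "as_binary_mask", "binarize", "crop", "paste"]


@dataclass(frozen=True)
class SurroundingBox:
    """A loose user-drawn box around the lesion, half-open in both axes.

    The box is deliberately *not* a tight bounding box: users draw it with
    slack, and the training procedure emulates that slack with random jitter.
    """

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate box {self!r}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"negative box corner {self!r}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def area(self) -> int:
        return self.height * self.width

    def contains(self, row: int, col: int) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right

    def clipped(self, height: int, width: int) -> "SurroundingBox":
        """Intersect with the image extent ``height x width``."""
        return SurroundingBox(
            max(0, self.top),
            max(0, self.left),
            min(height, self.bottom),
            min(width, self.right),
        )

    def to_json_dict(self) -> dict:
        return {"top": self.top, "left": self.left, "bottom": self.bottom, "right": self.right}

    @classmethod
    def from_json_dict(cls, d: dict) -> "SurroundingBox":
        return cls(int(d["top"]), int(d["left"]), int(d["bottom"]), int(d["right"]))


def as_binary_mask(values: np.ndarray) -> np.ndarray:
    """Validate and coerce ``values`` to a {0,1} uint8 mask."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask elements must be exactly 0 or 1")
    return arr.astype(np.uint8, copy=False)


def binarize(logits: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Threshold a real-valued map into a binary mask: 1 iff value > threshold.

    The default threshold of 0 matches maps in the logit domain, which is the
    domain the residual fusion operates in.
    """
    arr = np.asarray(logits, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("binarize requires finite values")
    return (arr > threshold).astype(np.uint8)


def _check_box_in_extent(box: SurroundingBox, shape: tuple) -> None:
    h, w = shape[0], shape[1]
    if box.bottom > h or box.right > w:
        raise IndexError(f"box {box} exceeds extent {(h, w)}")


def crop(raster: np.ndarray, box: SurroundingBox) -> np.ndarray:
    """Return the sub-raster under ``box``. Works for 2-D masks and H x W x C images."""
    _check_box_in_extent(box, raster.shape)
    return raster[box.top : box.bottom, box.left : box.right].copy()


def paste(raster: np.ndarray, patch: np.ndarray, box: SurroundingBox) -> np.ndarray:
    """Inverse of :func:`crop`: write ``patch`` into ``raster`` at ``box`` (returns a copy)."""
    _check_box_in_extent(box, raster.shape)
    if patch.shape[:2] != (box.height, box.width):
        raise ValueError(f"patch shape {patch.shape[:2]} does not match box {box}")
    out = raster.copy()
    out[box.top : box.bottom, box.left : box.right] = patch
    return out
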