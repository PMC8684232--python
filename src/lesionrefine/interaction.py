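"""Simulation of user interactions: surrounding-box jitter and corrective clicks.

Two interaction channels drive the pipeline.  A *surrounding box* is a loose
box the user draws around the lesion; during training it is emulated by
jittering the tight bounding box of the ground truth by a uniform integer
offset per edge.  *Clicks* are corrective pokes on the two mistake classes of
a coarse segmentation: positive clicks mark pixels wrongly excluded
(false negatives), negative clicks mark pixels wrongly included
(false positives).  Training-time clicks are sampled uniformly at random,
without replacement, from the corresponding error set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SurroundingBox, as_binary_mask

__all__ = ["Click", "ClickSet", "tight_bbox", "jitter_box", "sample_clicks", "allocate_clicks"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Click:
    row: int
    col: int
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")


@dataclass
class ClickSet:
    """Ordered positive (S1) and negative (S2) click lists, in crop coordinates."""

    positives: list = field(default_factory=list)
    negatives: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for c in list(self.positives) + list(self.negatives):
            key = (c.row, c.col, c.polarity)
            if key in seen:
                raise ValueError(f"duplicate click {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    def add(self, click: Click) -> None:
        pool = self.positives if click.polarity == POSITIVE else self.negatives
        if any((c.row, c.col) == (click.row, click.col) for c in pool):
            raise ValueError(f"duplicate click at ({click.row}, {click.col})")
        pool.append(click)

    def extend(self, clicks) -> None:
        for c in clicks:
            self.add(c)

    def merged(self, other: "ClickSet") -> "ClickSet":
        return ClickSet(list(self.positives) + list(other.positives),
                        list(self.negatives) + list(other.negatives))

    def to_json_dict(self) -> dict:
        return {
            "positive": [[c.row, c.col] for c in self.positives],
            "negative": [[c.row, c.col] for c in self.negatives],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ClickSet":
        return cls(
            [Click(int(r), int(c), POSITIVE) for r, c in d.get("positive", [])],
            [Click(int(r), int(c), NEGATIVE) for r, c in d.get("negative", [])],
        )


def tight_bbox(mask: np.ndarray) -> SurroundingBox:
    """Smallest half-open box containing every foreground pixel of ``mask``."""
    m = as_binary_mask(mask)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        raise ValueError("tight_bbox of an empty mask")
    return SurroundingBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def jitter_box(
    box: SurroundingBox,
    max_jitter: int,
    extent: tuple,
    rng: np.random.Generator,
) -> SurroundingBox:
    """Shift each edge independently by a uniform integer in [-max_jitter, +max_jitter].

    Offsets are clamped to the image extent; a draw that degenerates the box
    (non-positive height or width) is resampled, preserving the uniform-offset
    model on the valid draws.  ``max_jitter=0`` returns the box unchanged.
    """
    if max_jitter < 0:
        raise ValueError("max_jitter must be >= 0")
    h, w = extent
    if box.bottom > h or box.right > w:
        raise ValueError(f"box {box} outside extent {extent}")
    if max_jitter == 0:
        return box
    while True:
        dt, dl, db, dr = rng.integers(-max_jitter, max_jitter + 1, size=4)
        top = min(max(box.top + int(dt), 0), h - 1)
        left = min(max(box.left + int(dl), 0), w - 1)
        bottom = min(max(box.bottom + int(db), 1), h)
        right = min(max(box.right + int(dr), 1), w)
        if bottom > top and right > left:
            return SurroundingBox(top, left, bottom, right)


def error_sets(pred: np.ndarray, gt: np.ndarray) -> tuple:
    """Return (false-negative pixels, false-positive pixels) as (N,2) index arrays."""
    p = as_binary_mask(pred).astype(bool)
    g = as_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError("pred/gt shape mismatch")
    fn = np.argwhere(~p & g)
    fp = np.argwhere(p & ~g)
    return fn, fp


def sample_clicks(
    pred: np.ndarray,
    gt: np.ndarray,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
) -> ClickSet:
    """Sample corrective clicks uniformly without replacement from the error sets.

    Positive clicks come from the false-negative set (``~pred & gt``), negative
    clicks from the false-positive set (``pred & ~gt``).  If an error set holds
    fewer pixels than requested, as many as available are returned.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("click counts must be >= 0")
    fn, fp = error_sets(pred, gt)

    def draw(pixels: np.ndarray, n: int, polarity: str) -> list:
        k = min(n, len(pixels))
        if k == 0:
            return []
        idx = rng.choice(len(pixels), size=k, replace=False)
        return [Click(int(pixels[i, 0]), int(pixels[i, 1]), polarity) for i in idx]

    return ClickSet(draw(fn, n_pos, POSITIVE), draw(fp, n_neg, NEGATIVE))


def allocate_clicks(n_total: int, n_fn: int, n_fp: int) -> tuple:
    """Split a click budget between the two error sets, proportional to their areas.

    Largest-remainder allocation; ties favour the positive (false-negative)
    side.  Each share is capped by its set size and unused budget flows to the
    other side when it still has pixels.
    """
    if n_total <= 0 or n_fn + n_fp == 0:
        return 0, 0
    total = n_fn + n_fp
    raw_pos = n_total * n_fn / total
    n_pos = int(raw_pos)
    n_neg = int(n_total * n_fp / total)
    if n_pos + n_neg < n_total:  # hand the remainder to the larger fraction, tie -> positive
        if raw_pos - n_pos >= (n_total * n_fp / total) - n_neg:
            n_pos += 1
        else:
            n_neg += 1
    # cap by availability, spill leftover budget to the other side
    spill_pos = max(0, n_pos - n_fn)
    spill_neg = max(0, n_neg - n_fp)
    n_pos = min(n_pos, n_fn) + min(spill_neg, max(0, n_fn - min(n_pos, n_fn)))
    n_neg = min(n_neg, n_fp) + min(spill_pos, max(0, n_fp - n_neg))
    return min(n_pos, n_fn), min(n_neg, n_fp)
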