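"""Synthetic dermoscopy-like image/mask pairs with controllable difficulty.

Each sample is a skin-toned background (smooth gradient + Gaussian noise)
holding a single darker, blob-shaped lesion.  The lesion interior is the
region rho <= r(theta) of a star-convex radial-harmonic contour

    r(theta) = r0 * (1 + sum_k a_k * sin(k * theta + phi_k)),

which guarantees a single connected component and gives an exact analytic
interior test for the ground-truth mask.  The mask is defined *before* the
boundary blur, so ground truth stays crisp while the image has soft edges —
the way dermoscopy annotations relate to the photographs they label.

With probability ``artifact_prob`` a distractor is added — a dark blot or a
hair-like streak — placed so it never enters the lesion mask.  Distractors
are darker than skin, so an intensity-driven coarse segmenter tends to
include them, producing exactly the false-positive mistakes the click-guided
refinement stage exists to remove.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import as_binary_mask

__all__ = ["LesionSpec", "generate_sample", "generate_dataset", "load_dataset", "Sample"]


@dataclass(frozen=True)
class LesionSpec:
    """Generation parameters; defaults target a 96 x 96 desk-scale image."""

    image_size: int = 96
    lesion_radius_range: tuple = (14.0, 26.0)  # pixels
    n_harmonics: int = 4                        # radial perturbation terms (k = 2..)
    harmonic_amplitude: float = 0.14            # max |a_k|, fraction of r0
    lesion_contrast: float = 70.0               # intensity drop inside the lesion
    noise_sd: float = 7.0                       # additive Gaussian noise, intensity units
    artifact_prob: float = 0.5                  # chance of a distractor blot/streak
    blur_sigma: float = 1.2                     # boundary softness, pixels
    fade_range: tuple = (1.0, 9.0)              # width of the faint lesion rim, pixels
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < self.image_size / 2):
            raise ValueError("lesion radius range must be positive and fit the image")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must be in [0, 1]")

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class Sample:
    sample_id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 {0, 1}


_BASE_SKIN = np.array([205.0, 160.0, 140.0])
_MARGIN = 3  # lesion kept strictly inside the frame by this many pixels


def _blob_mask(size: int, cy: float, cx: float, r0: float, amps, phases) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r = np.full_like(theta, r0)
    for k, (a, ph) in enumerate(zip(amps, phases), start=2):
        r += r0 * a * np.sin(k * theta + ph)
    return (rho <= r).astype(np.uint8)


def _soft_edge(mask: np.ndarray, sigma: float) -> np.ndarray:
    m = mask.astype(float)
    return ndimage.gaussian_filter(m, sigma) if sigma > 0 else m


def _add_blot(img, lesion_mask, rng, contrast, blur_sigma, tint):
    """A lesion-coloured blot close to (but never touching) the lesion, so it
    falls inside the surrounding-box crop and fools an intensity-driven
    segmenter into a false positive."""
    size = lesion_mask.shape[0]
    dist = ndimage.distance_transform_edt(1 - lesion_mask)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(30):
        r = rng.uniform(2.5, 6.0)
        # candidate centres: clear of the lesion by 2 px but within ~10 px of it
        cand = np.argwhere((dist > r + 2) & (dist < r + 12))
        cand = cand[(cand[:, 0] > r) & (cand[:, 0] < size - 1 - r)
                    & (cand[:, 1] > r) & (cand[:, 1] < size - 1 - r)]
        if len(cand) == 0:
            continue
        cy, cx = cand[rng.integers(len(cand))]
        blot = (np.hypot(yy - cy, xx - cx) <= r).astype(np.uint8)
        if not (blot & lesion_mask).any():
            alpha = _soft_edge(blot, blur_sigma)
            alpha[lesion_mask.astype(bool)] = 0.0  # never darken annotated pixels
            img -= alpha[..., None] * contrast * rng.uniform(0.8, 1.2) * tint[None, None, :]
            return
    # no collision-free placement found; skip the distractor


def _add_streak(img, lesion_mask, rng, blur_sigma):
    """A thin dark hair-like polyline, occluded wherever it would cross the lesion."""
    size = lesion_mask.shape[0]
    n = 40
    t = np.linspace(0, 1, n)
    p0 = rng.uniform(0, size - 1, size=2)
    p1 = rng.uniform(0, size - 1, size=2)
    bow = rng.uniform(-0.25, 0.25) * size
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    norm = np.linalg.norm(normal)
    if norm < 1e-6:
        return
    normal /= norm
    pts = p0[None] + t[:, None] * (p1 - p0)[None] + (bow * np.sin(np.pi * t))[:, None] * normal
    canvas = np.zeros((size, size))
    idx = np.clip(np.round(pts).astype(int), 0, size - 1)
    canvas[idx[:, 0], idx[:, 1]] = 1.0
    canvas = ndimage.grey_dilation(canvas, size=(2, 2))
    canvas[lesion_mask.astype(bool)] = 0.0
    alpha = _soft_edge(canvas, max(blur_sigma * 0.5, 0.4))
    alpha[lesion_mask.astype(bool)] = 0.0  # never darken annotated pixels
    img -= np.clip(alpha, 0, 1)[..., None] * rng.uniform(45.0, 80.0)


def generate_sample(spec: LesionSpec, rng: np.random.Generator) -> tuple:
    """Draw one (RGB image, binary mask) pair from ``spec`` using ``rng``."""
    size = spec.image_size

    # skin background: jittered base colour + a smooth directional gradient + noise
    base = _BASE_SKIN + rng.uniform(-15, 15, size=3)
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / max(size - 1, 1)
    direction = rng.uniform(-1, 1, size=2)
    ramp = (direction[0] * yy + direction[1] * xx) * rng.uniform(0, 20)
    img = base[None, None, :] + ramp[..., None]

    # star-convex lesion, strictly inside the frame
    lo, hi = spec.lesion_radius_range
    r0 = rng.uniform(lo, hi)
    max_r = r0 * (1 + spec.n_harmonics * spec.harmonic_amplitude)
    pad = min(max_r + _MARGIN, size / 2 - 1)
    cy, cx = rng.uniform(pad, size - 1 - pad, size=2)
    amps = rng.uniform(-spec.harmonic_amplitude, spec.harmonic_amplitude, size=spec.n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_harmonics)
    mask = _blob_mask(size, cy, cx, r0, amps, phases)
    mask[0, :] = mask[-1, :] = 0
    mask[:, 0] = mask[:, -1] = 0

    # pigment fades toward the rim: the annotated boundary sits in a faint
    # margin rather than on a crisp intensity edge (as in real dermoscopy)
    fade = rng.uniform(*spec.fade_range)
    depth = ndimage.distance_transform_edt(mask)
    alpha = _soft_edge(np.clip(depth / max(fade, 1e-6), 0.0, 1.0), spec.blur_sigma)
    tint = np.array([1.0, 1.15, 1.25])  # lesions skew brown: blue channel drops most
    # per-image contrast spread: weak-contrast lesions are genuinely harder
    contrast = spec.lesion_contrast * rng.uniform(0.5, 1.2)
    img -= alpha[..., None] * contrast * tint[None, None, :]

    if rng.uniform() < spec.artifact_prob:
        if rng.uniform() < 0.7:
            _add_blot(img, mask, rng, contrast, spec.blur_sigma, tint)
        else:
            _add_streak(img, mask, rng, spec.blur_sigma)

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, as_binary_mask(mask)


def generate_samples(spec: LesionSpec, n: int, seed: int) -> list:
    """n in-memory samples; sample i uses the derived seed ``seed + i``."""
    out = []
    for i in range(n):
        rng = np.random.default_rng(seed + i)
        img, mask = generate_sample(spec, rng)
        out.append(Sample(sample_id=f"synth_{seed + i:08d}", image=img, mask=mask))
    return out


def generate_dataset(spec: LesionSpec, n: int, seed: int, out_dir) -> pd.DataFrame:
    """Write n PNG image/mask pairs plus a manifest CSV; returns the manifest."""
    from .io import write_image, write_mask  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in generate_samples(spec, n, seed):
        img_path = out_dir / f"{s.sample_id}.png"
        mask_path = out_dir / f"{s.sample_id}_mask.png"
        write_image(img_path, s.image)
        write_mask(mask_path, s.mask)
        rows.append(
            {
                "id": s.sample_id,
                "image": img_path.name,
                "mask": mask_path.name,
                "spec_hash": spec.content_hash(),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path) -> list:
    """Read a generated dataset back into memory as a list of :class:`Sample`."""
    from .io import read_image, read_mask

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    return [
        Sample(row["id"], read_image(root / row["image"]), read_mask(root / row["mask"]))
        for _, row in manifest.iterrows()
    ]
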