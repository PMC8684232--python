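"""File formats: PNG images/masks, JSON boxes and clicks, CSV metric reports.

Masks on disk are single-channel 8-bit PNGs with 0 = background and
255 = lesion; in memory they are {0, 1} uint8 arrays.  Undefined metric
values (NaN) are written as empty CSV cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import SurroundingBox, as_binary_mask
from .interaction import ClickSet

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "read_box", "write_box", "read_clicks", "write_clicks",
    "write_metrics_csv",
]


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return as_binary_mask((arr >= 128).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    arr = as_binary_mask(mask) * np.uint8(255)
    Image.fromarray(arr, mode="L").save(path)


def read_box(path) -> SurroundingBox:
    with open(path) as fh:
        return SurroundingBox.from_json_dict(json.load(fh))


def write_box(path, box: SurroundingBox) -> None:
    with open(path, "w") as fh:
        json.dump(box.to_json_dict(), fh)


def read_clicks(path) -> ClickSet:
    with open(path) as fh:
        return ClickSet.from_json_dict(json.load(fh))


def write_clicks(path, clicks: ClickSet) -> None:
    with open(path, "w") as fh:
        json.dump(clicks.to_json_dict(), fh)


def write_metrics_csv(path, rows: list) -> pd.DataFrame:
    """rows: list of dicts with sample_id plus acc/sen/spe/dic/iou (NaN allowed)."""
    df = pd.DataFrame(rows, columns=["sample_id", "acc", "sen", "spe", "dic", "iou"])
    df.to_csv(path, index=False, na_rep="")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
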