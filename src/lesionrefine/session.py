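"""Interactive refinement sessions and the batch evaluation protocols.

A session runs the full user-facing pipeline on one image: crop under the
surrounding box, one coarse forward pass (features cached), then any number
of click-refinement steps that reuse the cached features — the encoder runs
exactly once per session.  Batch protocols build on sessions:

* ``evaluate_dataset`` — coarse vs. click-refined metrics at a fixed click
  budget, with per-sample rows, dataset means and improvement deltas;
* ``clicks_to_target`` — mean number of interactions (the surrounding box
  counted as 2 clicks, then one click per refinement step) needed to reach a
  target IoU;
* ``ablation_harness`` — trains one model per global-context variant under
  identical seeds and data and tabulates the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import SurroundingBox, binarize, crop, paste
from .guidance import GuidanceConfig, fuse, gaussian_guidance
from .interaction import ClickSet, allocate_clicks, error_sets, jitter_box, sample_clicks, tight_bbox
from .metrics import MetricsReport, compute_metrics, confusion_counts
from .networks import TwoStageModel
from .training import (TrainConfig, mine_hard_examples, resize_image, resize_logits,
                       resize_mask, train_click, train_sbox)

__all__ = ["RefineSession", "refine_session", "EvalReport", "evaluate_dataset",
           "clicks_to_target", "ablation_harness"]

_METRIC_COLS = ("acc", "sen", "spe", "dic", "iou")


class RefineSession:
    """One interactive segmentation session on a single image.

    Clicks are given in *crop coordinates* — (row, col) inside the box, at the
    crop's native resolution.  Metrics (when ground truth is supplied) are
    evaluated on the native crop, the region the pipeline operates on.
    """

    def __init__(self, model: TwoStageModel, image: np.ndarray, box: SurroundingBox,
                 gt: np.ndarray | None = None, guidance: GuidanceConfig | None = None,
                 threshold: float = 0.0):
        h, w = image.shape[:2]
        if box.bottom > h or box.right > w:
            raise IndexError(f"box {box} outside image extent {(h, w)}")
        self.model = model
        self.image = image
        self.box = box
        self.threshold = threshold
        cs = model.cfg.crop_size
        self.guidance = guidance or GuidanceConfig().scaled_for(cs)
        self.gt_crop = None if gt is None else crop(gt, box)

        x = model.preprocess(resize_image(crop(image, box), (cs, cs))[None])
        b, ctx = model.sbox_forward(x)
        self._b = b[0, 0]
        self._ctx = ctx
        self._pos_pts: list = []   # click positions on the crop_size grid
        self._neg_pts: list = []
        self.clicks = ClickSet()   # the same clicks in native crop coordinates
        self._f = self._b.copy()
        self._c = np.zeros_like(self._b)
        self.metrics_history: list = []
        self._record_metrics()

    # -- geometry helpers ---------------------------------------------------
    def _to_grid(self, row: float, col: float) -> tuple:
        """Native crop coordinates -> positions on the crop_size grid
        (half-pixel-centred, so sub-stride positions survive the resize)."""
        cs = self.model.cfg.crop_size
        r = (row + 0.5) * cs / self.box.height - 0.5
        c = (col + 0.5) * cs / self.box.width - 0.5
        return (min(max(r, 0.0), cs - 1), min(max(c, 0.0), cs - 1))

    # -- state --------------------------------------------------------------
    @property
    def fused_logits(self) -> np.ndarray:
        return self._f

    @property
    def coarse_logits(self) -> np.ndarray:
        return self._b

    def prediction_grid(self) -> np.ndarray:
        """Current binary mask on the crop_size grid."""
        return binarize(self._f, self.threshold)

    def prediction_crop(self) -> np.ndarray:
        """Current binary mask at the crop's native resolution."""
        native = resize_logits(self._f, (self.box.height, self.box.width))
        return binarize(native, self.threshold)

    def full_frame_mask(self) -> np.ndarray:
        """Paste the crop result back; pixels outside the box are background."""
        frame = np.zeros(self.image.shape[:2], dtype=np.uint8)
        return paste(frame, self.prediction_crop(), self.box)

    def gt_grid(self) -> np.ndarray:
        cs = self.model.cfg.crop_size
        return resize_mask(self.gt_crop, (cs, cs))

    def _record_metrics(self) -> None:
        if self.gt_crop is not None:
            self.metrics_history.append(
                compute_metrics(confusion_counts(self.prediction_crop(), self.gt_crop))
            )

    # -- refinement ---------------------------------------------------------
    def add_clicks(self, clicks) -> MetricsReport | None:
        """Append clicks (native crop coordinates) and run one refinement pass."""
        clicks = list(clicks.positives) + list(clicks.negatives) if isinstance(clicks, ClickSet) else list(clicks)
        for c in clicks:
            if not (0 <= c.row < self.box.height and 0 <= c.col < self.box.width):
                raise IndexError(f"click ({c.row}, {c.col}) outside crop "
                                 f"{(self.box.height, self.box.width)}")
            self.clicks.add(c)
            pts = self._pos_pts if c.polarity == "positive" else self._neg_pts
            pts.append(self._to_grid(c.row, c.col))
        self._refine()
        return self.metrics_history[-1] if self.gt_crop is not None else None

    def add_grid_clicks(self, pos_pts, neg_pts) -> None:
        """Append clicks already on the crop_size grid (used by the simulated
        evaluation protocols) and refine."""
        self._pos_pts.extend(tuple(p) for p in pos_pts)
        self._neg_pts.extend(tuple(p) for p in neg_pts)
        self._refine()

    def _refine(self) -> None:
        cs = self.model.cfg.crop_size
        g1 = gaussian_guidance(self._pos_pts, self.guidance.radius, (cs, cs))
        g2 = gaussian_guidance(self._neg_pts, self.guidance.radius, (cs, cs))
        pts = self._pos_pts + self._neg_pts
        if pts:
            w = np.sum([gaussian_guidance([p], self.guidance.weight_radius, (cs, cs))
                        for p in pts], axis=0)
        else:
            w = np.zeros((cs, cs))
        c = self.model.click_forward(self._ctx, np.stack([g1, g2])[None])[0, 0]
        self._c = c
        self._f = fuse(self._b, c, w)
        self._record_metrics()

    @property
    def n_refinement_steps(self) -> int:
        return len(self.metrics_history) - 1 if self.gt_crop is not None else None


def refine_session(image, box, model, click_steps=(), gt=None,
                   guidance: GuidanceConfig | None = None) -> RefineSession:
    """Run a session: coarse pass, then one refinement per element of
    ``click_steps`` (each an iterable of :class:`Click` in crop coordinates)."""
    s = RefineSession(model, image, box, gt=gt, guidance=guidance)
    for step in click_steps:
        s.add_clicks(step)
    return s


# ---------------------------------------------------------------------------
# batch protocols
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_sample: pd.DataFrame
    n_clicks: int

    @property
    def means(self) -> dict:
        return {c: float(self.per_sample[c].mean()) for c in self.per_sample.columns
                if c != "sample_id"}

    def summary(self) -> pd.DataFrame:
        m = self.means
        return pd.DataFrame(
            [
                {"stage": "sbox", **{k: m[f"base_{k}"] for k in _METRIC_COLS}},
                {"stage": f"sbox+click({self.n_clicks})",
                 **{k: m[f"refined_{k}"] for k in _METRIC_COLS}},
                {"stage": "delta", **{k: m[f"delta_{k}"] for k in _METRIC_COLS}},
            ]
        )


def _simulate_refine(session: RefineSession, n_clicks: int, rng) -> None:
    """Sample the click budget from the current error sets (on the network
    grid, the frame training used) and refine once."""
    if n_clicks <= 0:
        return
    pred = session.prediction_grid()
    gt = session.gt_grid()
    fn, fp = error_sets(pred, gt)
    n_pos, n_neg = allocate_clicks(n_clicks, len(fn), len(fp))
    cs_clicks = sample_clicks(pred, gt, n_pos, n_neg, rng)
    if len(cs_clicks) == 0:
        return
    session.add_grid_clicks([(c.row, c.col) for c in cs_clicks.positives],
                            [(c.row, c.col) for c in cs_clicks.negatives])


def evaluate_dataset(model: TwoStageModel, dataset, n_clicks: int,
                     rng: np.random.Generator, eval_jitter: int = 0,
                     guidance: GuidanceConfig | None = None) -> EvalReport:
    """Coarse vs. refined metrics at a fixed click budget (single fused pass)."""
    if not dataset:
        raise ValueError("dataset is empty")
    rows = []
    for s in dataset:
        image, mask = (s.image, s.mask) if hasattr(s, "image") else (s[0], s[1])
        sid = getattr(s, "sample_id", f"sample_{len(rows)}")
        box = tight_bbox(mask)
        if eval_jitter > 0:
            box = jitter_box(box, eval_jitter, mask.shape, rng)
        session = RefineSession(model, image, box, gt=mask, guidance=guidance)
        base = session.metrics_history[0]
        _simulate_refine(session, n_clicks, rng)
        refined = session.metrics_history[-1]
        row = {"sample_id": sid}
        for k in _METRIC_COLS:
            bv, rv = getattr(base, k), getattr(refined, k)
            row[f"base_{k}"] = bv
            row[f"refined_{k}"] = rv
            row[f"delta_{k}"] = rv - bv
        rows.append(row)
    return EvalReport(per_sample=pd.DataFrame(rows), n_clicks=n_clicks)


@dataclass
class ClicksToTargetResult:
    per_sample: pd.DataFrame
    target_iou: float
    max_clicks: int

    @property
    def mean_clicks(self) -> float:
        return float(self.per_sample["clicks"].mean())

    @property
    def n_censored(self) -> int:
        return int(self.per_sample["censored"].sum())


def clicks_to_target(model: TwoStageModel, dataset, target_iou: float,
                     max_clicks: int, rng: np.random.Generator,
                     guidance: GuidanceConfig | None = None) -> ClicksToTargetResult:
    """Interactions needed to reach ``target_iou`` per sample.

    The surrounding box costs 2 clicks; each refinement step adds one click
    sampled from the larger current error set (ties favour positive).
    Samples still below target after ``max_clicks`` steps are *censored*:
    counted at ``2 + max_clicks`` and flagged.
    """
    if not 0 < target_iou <= 1:
        raise ValueError("target_iou must be in (0, 1]")
    if max_clicks < 0:
        raise ValueError("max_clicks must be >= 0")
    rows = []
    for s in dataset:
        image, mask = (s.image, s.mask) if hasattr(s, "image") else (s[0], s[1])
        sid = getattr(s, "sample_id", f"sample_{len(rows)}")
        session = RefineSession(model, image, tight_bbox(mask), gt=mask, guidance=guidance)
        iou = session.metrics_history[0].iou
        steps = 0
        clicked = set()
        while iou < target_iou and steps < max_clicks:
            pred, gt = session.prediction_grid(), session.gt_grid()
            fn, fp = error_sets(pred, gt)
            fn = [tuple(p) for p in fn if tuple(p) not in clicked]
            fp = [tuple(p) for p in fp if tuple(p) not in clicked]
            if not fn and not fp:
                break
            take_pos = len(fn) >= len(fp) if fn else False
            pool = fn if take_pos else fp
            pt = pool[int(rng.integers(len(pool)))]
            clicked.add(pt)
            if take_pos:
                session.add_grid_clicks([pt], [])
            else:
                session.add_grid_clicks([], [pt])
            iou = session.metrics_history[-1].iou
            steps += 1
        censored = iou < target_iou
        rows.append({"sample_id": sid,
                     "clicks": 2 + (max_clicks if censored else steps),
                     "iou": iou, "censored": censored})
    return ClicksToTargetResult(pd.DataFrame(rows), target_iou, max_clicks)


def ablation_harness(train_dataset, test_dataset, variants, mc, tc: TrainConfig,
                     click_tc: TrainConfig | None = None, n_clicks: int = 2,
                     guidance: GuidanceConfig | None = None) -> pd.DataFrame:
    """Train one model per global-context variant under identical seeds and
    data; tabulate coarse IoU and (optionally) click-refined IoU per variant."""
    if len(list(variants)) < 2 and len(list(variants)) != 1:
        raise ValueError("need at least one variant")
    rows = []
    for v in variants:
        model, _ = train_sbox(train_dataset, replace(mc, context=v), tc)
        rng = np.random.default_rng(tc.seed)
        report = evaluate_dataset(model, test_dataset, 0, rng, guidance=guidance)
        row = {"context": v, "sbox_iou": report.means["base_iou"]}
        if click_tc is not None:
            hard = mine_hard_examples(model, train_dataset, click_tc.hard_iou_threshold)
            if hard:
                train_click(model, hard, click_tc, guidance=guidance)
            rng = np.random.default_rng(tc.seed)
            refined = evaluate_dataset(model, test_dataset, n_clicks, rng, guidance=guidance)
            row["sbox_click_iou"] = refined.means["refined_iou"]
        rows.append(row)
    return pd.DataFrame(rows)
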