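"""Interactive sessions, batch evaluation, clicks-to-target, ablation harness."""

import numpy as np
import pytest

import lesionrefine as lr
from lesionrefine.training import with_overrides


@pytest.fixture
def sample(tiny_dataset):
    return tiny_dataset[45]


class TestRefineSession:
    def test_zero_click_session_equals_binarized_coarse_output(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        s = lr.refine_session(sample.image, box, trained_model, gt=sample.mask)
        assert np.array_equal(s.prediction_grid(), lr.binarize(s.coarse_logits))
        assert len(s.metrics_history) == 1

    def test_empty_click_refinement_is_bit_identical_to_coarse(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        s = lr.refine_session(sample.image, box, trained_model, gt=sample.mask)
        s.add_clicks([])  # a refinement pass with no clicks: W = 0 everywhere
        assert np.array_equal(s.fused_logits, s.coarse_logits)

    def test_features_cached_encoder_runs_once(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        before = trained_model.n_encoder_calls
        s = lr.RefineSession(trained_model, sample.image, box, gt=sample.mask)
        s.add_clicks([lr.Click(2, 2, "positive")])
        s.add_clicks([lr.Click(3, 3, "negative")])
        assert trained_model.n_encoder_calls == before + 1

    def test_click_count_never_decreases_and_history_tracks_steps(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        s = lr.RefineSession(trained_model, sample.image, box, gt=sample.mask)
        counts = [len(s.clicks)]
        s.add_clicks([lr.Click(1, 1, "positive")])
        counts.append(len(s.clicks))
        s.add_clicks([lr.Click(2, 2, "negative"), lr.Click(4, 4, "positive")])
        counts.append(len(s.clicks))
        assert counts == [0, 1, 3]
        assert len(s.metrics_history) == 3  # initial + one per refinement step

    def test_full_frame_mask_zero_outside_box(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        s = lr.RefineSession(trained_model, sample.image, box)
        full = s.full_frame_mask()
        assert full.shape == sample.image.shape[:2]
        outside = np.ones_like(full, dtype=bool)
        outside[box.top : box.bottom, box.left : box.right] = False
        assert full[outside].sum() == 0
        assert np.array_equal(full[box.top : box.bottom, box.left : box.right],
                              s.prediction_crop())

    def test_session_is_deterministic(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        masks = []
        for _ in range(2):
            s = lr.RefineSession(trained_model, sample.image, box)
            s.add_clicks([lr.Click(5, 5, "positive")])
            masks.append(s.full_frame_mask())
        assert np.array_equal(masks[0], masks[1])

    def test_click_outside_crop_rejected(self, trained_model, sample):
        box = lr.tight_bbox(sample.mask)
        s = lr.RefineSession(trained_model, sample.image, box)
        with pytest.raises(IndexError):
            s.add_clicks([lr.Click(box.height + 5, 0, "positive")])

    def test_box_outside_image_rejected(self, trained_model, sample):
        h, w = sample.image.shape[:2]
        with pytest.raises(IndexError):
            lr.RefineSession(trained_model, sample.image, lr.SurroundingBox(0, 0, h + 1, w))


class TestEvaluateDataset:
    def test_zero_click_budget_gives_zero_deltas(self, trained_model, tiny_dataset, rng):
        rep = lr.evaluate_dataset(trained_model, tiny_dataset[40:50], 0, rng)
        assert len(rep.per_sample) == 10
        for col in ("delta_acc", "delta_iou", "delta_dic"):
            assert np.allclose(rep.per_sample[col], 0.0)

    def test_delta_columns_recomputable(self, trained_model, tiny_dataset, rng):
        rep = lr.evaluate_dataset(trained_model, tiny_dataset[40:50], 2, rng)
        for k in ("acc", "sen", "spe", "dic", "iou"):
            assert np.allclose(
                rep.per_sample[f"delta_{k}"],
                rep.per_sample[f"refined_{k}"] - rep.per_sample[f"base_{k}"],
                equal_nan=True,
            )

    def test_empty_dataset_rejected(self, trained_model, rng):
        with pytest.raises(ValueError):
            lr.evaluate_dataset(trained_model, [], 2, rng)


class TestClicksToTarget:
    def test_trivial_target_costs_only_the_box(self, trained_model, tiny_dataset, rng):
        res = lr.clicks_to_target(trained_model, tiny_dataset[40:45], 0.01, 5, rng)
        assert res.mean_clicks == 2.0
        assert res.n_censored == 0

    def test_zero_click_budget_censors_below_target(self, trained_model, tiny_dataset, rng):
        res = lr.clicks_to_target(trained_model, tiny_dataset[40:50], 0.999, 0, rng)
        assert res.n_censored == len(res.per_sample)
        assert np.all(res.per_sample["clicks"] == 2)

    def test_mean_clicks_monotone_in_target(self, trained_model, tiny_dataset):
        r90 = lr.clicks_to_target(trained_model, tiny_dataset[40:55], 0.90, 6,
                                  np.random.default_rng(3))
        r95 = lr.clicks_to_target(trained_model, tiny_dataset[40:55], 0.95, 6,
                                  np.random.default_rng(3))
        assert r90.mean_clicks <= r95.mean_clicks

    def test_invalid_target_rejected(self, trained_model, tiny_dataset, rng):
        with pytest.raises(ValueError):
            lr.clicks_to_target(trained_model, tiny_dataset[:2], 1.5, 3, rng)


class TestAblationHarness:
    def test_single_variant_row_and_reproducibility(self, tiny_dataset):
        mc, tc = lr.desk_scale_config(seed=6)
        tc = with_overrides(tc, epochs=2, seed=6)
        t1 = lr.ablation_harness(tiny_dataset[:16], tiny_dataset[55:60], ["naive"], mc, tc)
        t2 = lr.ablation_harness(tiny_dataset[:16], tiny_dataset[55:60], ["naive"], mc, tc)
        assert len(t1) == 1 and t1.iloc[0]["context"] == "naive"
        assert t1.equals(t2)
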