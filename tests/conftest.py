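import numpy as np
import pytest

import lesionrefine as lr
from lesionrefine.training import with_overrides


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 desk-scale synthetic samples shared across tests."""
    return lr.generate_samples(lr.LesionSpec(), 60, seed=7)


@pytest.fixture(scope="session")
def guidance_cfg():
    return lr.GuidanceConfig().scaled_for(96)


@pytest.fixture(scope="session")
def trained_model(tiny_dataset, guidance_cfg):
    """A quickly but genuinely trained two-stage model (both heads)."""
    mc, tc = lr.desk_scale_config(seed=3)
    model, _ = lr.train_sbox(tiny_dataset[:40], mc, with_overrides(tc, epochs=6, seed=3))
    hard = lr.mine_hard_examples(model, tiny_dataset[:40], 0.95)
    if hard:
        lr.train_click(model, hard, with_overrides(tc, epochs=4, seed=3),
                       guidance=guidance_cfg)
    return model


@pytest.fixture
def untrained_model():
    return lr.TwoStageModel(lr.ModelConfig(seed=11))


def random_mask_pair(rng, h, w):
    pred = (rng.uniform(size=(h, w)) > 0.5).astype(np.uint8)
    gt = (rng.uniform(size=(h, w)) > 0.5).astype(np.uint8)
    return pred, gt
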