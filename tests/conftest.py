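"""Shared fixtures: phantom cohorts and a trained tiny model pair.

Training fixtures are session-scoped because fitting even the tiny network
is the expensive part of the suite; every test that needs a trained model
shares the same two fold models.
"""

from __future__ import annotations

import pytest
import numpy as np

from gliomaseg.brats_io import load_case
from gliomaseg.net import ModelConfig
from gliomaseg.phantom import PhantomSpec, generate_cohort
from gliomaseg.train import TrainConfig, make_folds, train_fold

COHORT_SEED = 11
TRAIN_SEED = 3
N_CASES = 6
N_FOLDS = 2
EPOCHS = 18

TINY_MODEL = dict(
    base_filters=8,
    input_size=(96, 96),
    transformer={"num_blocks": 1, "num_heads": 4, "embed_dim": 64, "mlp_dim": 128, "patch_size": 1},
    head_bias_prior=(0.92, 0.01, 0.05, 0.02),
)


@pytest.fixture(scope="session")
def phantom_cohort(tmp_path_factory):
    """Six phantom cases on disk in BraTS layout, plus loaded volumes."""
    root = tmp_path_factory.mktemp("cohort")
    paths = generate_cohort(N_CASES, root, seed=COHORT_SEED)
    cases = {p.name: load_case(p) for p in paths}
    return {"root": root, "paths": paths, "cases": cases}


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(**TINY_MODEL)


@pytest.fixture(scope="session")
def trained_folds(phantom_cohort, tiny_model_cfg):
    """Two fold models trained on the phantom cohort (case-level 2-fold CV)."""
    cases = phantom_cohort["cases"]
    tc = TrainConfig(epochs=EPOCHS, folds=N_FOLDS, seed=TRAIN_SEED, batch_size=8,
                     val_interval=3, crop_size=(96, 96), max_restarts=2)
    splits = make_folds(sorted(cases), N_FOLDS, seed=TRAIN_SEED)
    results = [train_fold(cases, tr, va, tc, tiny_model_cfg, fold=i)
               for i, (tr, va) in enumerate(splits)]
    return {"results": results, "splits": splits, "train_cfg": tc, "cases": cases}


@pytest.fixture(scope="session")
def single_phantom():
    """One deterministic default phantom case (volume + labels)."""
    from gliomaseg.phantom import generate_case

    spec = PhantomSpec(seed=7)
    vol, lab = generate_case(spec)
    return spec, vol, lab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
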