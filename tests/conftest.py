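"""Shared fixtures.

The expensive trained-model fixture is session-scoped: the desk-scale
segmentation network is trained once on the synthetic distribution and
shared by every test that needs a converged model.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mudrop.grid import default_grid

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from mudrop.segmentation import (ModelSpec, build_model, desk_training_config,
                                 resize_frames, train)
from mudrop.synthetic import make_arrays

TRAIN_N = 400
VAL_N = 100
DATA_SEED = 42
WORK_RES = 64   # desk-scale working resolution of the trained model


@pytest.fixture()
def grid():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """400 training + 100 validation frames of the synthetic distribution."""
    images, masks = make_arrays(TRAIN_N + VAL_N, seed=DATA_SEED)
    return ((images[:TRAIN_N], masks[:TRAIN_N]),
            (images[TRAIN_N:], masks[TRAIN_N:]))


@pytest.fixture(scope="session")
def trained_model(synthetic_dataset):
    """Width-scaled network trained to convergence on the synthetic set."""
    (tr_i, tr_m), (va_i, va_m) = synthetic_dataset
    spec = ModelSpec(base_width=64, width_scale=0.25,
                     working_resolution=WORK_RES)
    net = build_model(spec, seed=DATA_SEED)
    config = desk_training_config(seed=DATA_SEED)
    ti, tm = resize_frames(tr_i, tr_m, WORK_RES)
    vi, vm = resize_frames(va_i, va_m, WORK_RES)
    history = train(net, ti, tm, vi, vm, config)
    return net, spec, config, history
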