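"""Shared fixtures.

The expensive end-to-end experiment (train a tiny generator on lesion-free
phantoms, run the 9-seed anomaly pipeline on a 20+20 test set) is computed
once per session and shared by the training, anomaly and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mammogan import anomaly, phantom, preprocess, stylegen

# study conditions for the scaled end-to-end experiment
E2E_RESOLUTION = 32
E2E_N_TRAIN = 300
E2E_TRAIN_STEPS = 1200
E2E_SNAPSHOT_INTERVAL = 200
E2E_N_TEST_PER_CLASS = 20
E2E_N_SEEDS = 9
E2E_PROJECTION_STEPS = 200
E2E_DATA_SEED = 100
E2E_TEST_SEED = 5000
E2E_TRAIN_SEED = 1


@pytest.fixture(scope="session")
def preprocess_config():
    return preprocess.PreprocessConfig(target_size=E2E_RESOLUTION)


@pytest.fixture(scope="session")
def phantom_pair():
    """One lesion-free and one lesioned phantom from the same base seed."""
    normal = phantom.generate_phantom(phantom.PhantomParams(seed=7))
    lesion = phantom.generate_phantom(
        phantom.PhantomParams(seed=7, lesion_present=True, lesion_contrast=200.0, lesion_radius=10)
    )
    return normal, lesion


@pytest.fixture(scope="session")
def tiny_generator():
    """A small randomly initialised generator (16x16) for mechanics tests."""
    cfg = stylegen.GeneratorConfig(resolution=16, base_channels=16, z_dim=32, w_dim=32, seed=3)
    return stylegen.GeneratorModel.initialize(cfg)


@pytest.fixture(scope="session")
def e2e_experiment(preprocess_config):
    """Train on lesion-free phantoms, then score a 20+20 labelled test set."""
    train_recs = phantom.generate_dataset(E2E_N_TRAIN, 0, seed=E2E_DATA_SEED)
    train_imgs = [preprocess.preprocess_phantom(r, preprocess_config) for r in train_recs]
    cfg = stylegen.GeneratorConfig(resolution=E2E_RESOLUTION, seed=E2E_TRAIN_SEED)
    final_model, history = stylegen.train(
        train_imgs,
        cfg,
        steps=E2E_TRAIN_STEPS,
        snapshot_interval=E2E_SNAPSHOT_INTERVAL,
    )
    best = stylegen.select_best_snapshot(history, config=cfg)
    test_recs = phantom.generate_dataset(
        E2E_N_TEST_PER_CLASS, E2E_N_TEST_PER_CLASS, seed=E2E_TEST_SEED
    )
    report = anomaly.run_pipeline(
        test_recs,
        best,
        n_seeds=E2E_N_SEEDS,
        steps=E2E_PROJECTION_STEPS,
        config=preprocess_config,
    )
    return {
        "config": cfg,
        "history": history,
        "final_model": final_model,
        "best_model": best,
        "report": report,
    }
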