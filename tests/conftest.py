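"""Shared fixtures.

The expensive artifacts — the desk-scale overfit training runs used by the
capability tests — are session-scoped so the suite trains each configuration
exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import neuroseg3d as ns

# desk-scale capability-run settings: 32³ single phantom, 3 structures,
# default architecture hyperparameters, <=500 optimizer steps on one CPU
OVERFIT_SHAPE = (32, 32, 32)
OVERFIT_STRUCTURES = 3
OVERFIT_MAX_STEPS = 500
OVERFIT_SEED = 7


@pytest.fixture(scope="session")
def overfit_phantom():
    """One normalized 32³ phantom with 3 structures (the training 'set')."""
    spec = ns.PhantomSpec(shape=OVERFIT_SHAPE, n_structures=OVERFIT_STRUCTURES,
                          seed=OVERFIT_SEED)
    img, lab = ns.generate_phantom(spec)
    img = ns.normalize_intensity(img)
    return img, lab


def _model_config(patch_resolution: int) -> ns.ModelConfig:
    return ns.ModelConfig(input_shape=OVERFIT_SHAPE + (1,),
                          n_classes=OVERFIT_STRUCTURES + 1,
                          patch_resolution=patch_resolution, seed=0)


@pytest.fixture(scope="session")
def overfit_run(overfit_phantom):
    """Train the default (P=8) configuration to fit the single phantom.

    Early-stops once training macro Dice reaches 0.97, capped at 500 steps.
    Returns (network, history, steps_used).
    """
    img, lab = overfit_phantom
    cfg = _model_config(patch_resolution=8)
    tcfg = ns.TrainConfig(batch_size=1, max_epochs=OVERFIT_MAX_STEPS,
                          eval_every=25, patience=10 ** 6, seed=0,
                          stop_at_dice=0.97)
    net, history = ns.train(cfg, tcfg, [(img.voxels, lab.voxels)])
    return net, history, history[-1]["steps"]


@pytest.fixture(scope="session")
def p16_run(overfit_phantom, overfit_run):
    """Train the P=16 configuration with the same step budget the P=8 run used."""
    _, _, steps = overfit_run
    img, lab = overfit_phantom
    cfg = _model_config(patch_resolution=16)
    tcfg = ns.TrainConfig(batch_size=1, max_epochs=steps, eval_every=25,
                          patience=10 ** 6, seed=0)
    net, history = ns.train(cfg, tcfg, [(img.voxels, lab.voxels)],
                            max_steps=steps)
    return net, history, steps


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_model_cfg():
    """A fast-forward model configuration for unit tests."""
    return ns.ModelConfig(input_shape=(8, 8, 8, 1), n_classes=3,
                          n_transformer_layers=1, n_heads=2, hidden_size=8,
                          mlp_size=12, dropout_rate=0.0, patch_resolution=4,
                          encoder_channels=(3,), seed=0)
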