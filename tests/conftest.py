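"""Shared fixtures: small synthetic stacks and a trained bouton classifier.

Session-scoped because stack rendering and forest training are the slow
parts of the suite; every test works on its own views/copies.
"""

from __future__ import annotations

import numpy as np
import pytest

import axonquant as aq
from axonquant.boutons import (
    compute_feature_stack,
    labels_from_truth,
    train_bouton_classifier,
)

TEST_SHAPE = (48, 72, 72)


@pytest.fixture(scope="session")
def clean_stack():
    """Noiseless, bouton-free stack with known centerlines."""
    params = aq.SimParams(
        stack_shape=TEST_SHAPE, n_axons=3, noise_gaussian_sd=0.0,
        bouton_rate_per_um=0.0, seed=7,
    )
    stack, truth = aq.generate_axon_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def bouton_stack():
    """Default-noise stack bearing boutons, for segmentation tests."""
    params = aq.SimParams(stack_shape=TEST_SHAPE, n_axons=3, bouton_rate_per_um=0.3, seed=5)
    stack, truth = aq.generate_axon_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def bouton_classifier(bouton_stack):
    """Random forest trained on ground-truth-derived labels."""
    params, stack, truth = bouton_stack
    labels = labels_from_truth(stack, truth, axon_radius_um=params.axon_radius_um, seed=5)
    features = compute_feature_stack(stack)
    return train_bouton_classifier(features, labels, seed=5)


@pytest.fixture()
def straight_tube():
    """Single straight axis-aligned tube: 100 centerline voxels at 0.09 um."""
    vs = 0.09
    line = np.array([[2.0, 2.0, i * vs] for i in range(100)])
    params = aq.SimParams(
        stack_shape=(45, 45, 100), n_axons=1, noise_gaussian_sd=0.0,
        bouton_rate_per_um=0.0, seed=1,
    )
    stack, truth = aq.render_axon_stack([line], params)
    return line, stack, truth
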