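"""Shared fixtures: phantom data and a trained tiny classifier.

The trained model is session-scoped because seeded training is the most
expensive setup step and several suites (CAM smoke checks, end-to-end
volumetry) share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluidcam.classifier import ModelConfig, build_classifier, make_examples, train
from fluidcam.phantom import PhantomSpec, generate_cscan, make_classification_slices

TRAIN_SEED = 0
N_TRAIN_POS = 100
N_TRAIN_NEG = 100
TRAIN_EPOCHS = 20


@pytest.fixture(scope="session")
def training_slices():
    """200 phantom B-scans, half with an IRF lesion, half without."""
    return make_classification_slices(N_TRAIN_POS, N_TRAIN_NEG, "IRF", seed=100)


@pytest.fixture(scope="session")
def trained_tiny(training_slices):
    """Tiny-preset IRF classifier trained to separate the phantom task."""
    images, labels = training_slices
    model = build_classifier(
        ModelConfig.from_preset("tiny"), seed=TRAIN_SEED, pathology="IRF"
    )
    return train(model, make_examples(images, labels), TRAIN_EPOCHS, TRAIN_SEED)


@pytest.fixture(scope="session")
def phantom_cscan():
    """A small IRF-only phantom C-scan with ground truth."""
    spec = PhantomSpec(lesion_counts={"IRF": 1}, lesion_slice_fraction=0.7,
                       n_slices=8, seed=42)
    return generate_cscan(spec, "fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
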