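"""Shared fixtures: small synthetic corpora and one trained sanity model.

Heavy fixtures are session-scoped so the episodic training run and the
autoencoder are paid for once across the suite.
"""

import numpy as np
import pytest

from protoshape import augmentation as aug
from protoshape import autoencoder as ae
from protoshape import fewshot as fs
from protoshape import synthetic as syn


@pytest.fixture(scope="session")
def specs8():
    return syn.default_class_specs(8)


@pytest.fixture(scope="session")
def samples3():
    """3 well-separated classes x 8 coupled originals."""
    samples, _ = syn.gen_dataset(3, 8, seed=5)
    return samples


@pytest.fixture(scope="session")
def folds3(samples3):
    return aug.assign_folds(samples3, F=2, seed=0)


@pytest.fixture(scope="session")
def mask_batch(specs8):
    """20 binary masks spanning all 8 silhouette families."""
    return np.array([syn.gen_object(specs8[i % 8], "neutral", seed=i)[1]
                     for i in range(20)], dtype=float)


@pytest.fixture(scope="session")
def tiny_encoder(mask_batch):
    """Briefly trained shape encoder (enough for embedding plumbing)."""
    cfg = ae.AEConfig(n_blocks=3, use_pooling=False)
    encoder, _ = ae.train(mask_batch[:12], cfg, seed=0, n_steps=40)
    return encoder


@pytest.fixture(scope="session")
def sanity_run(samples3, folds3):
    """small_cnn meta-trained 5 epochs on separable 3-class images."""
    cfg = fs.TrainConfig(epochs=5, episodes_per_epoch=25, val_episodes=20)
    spec = fs.EpisodeSpec(K=3, H=2, J=1)
    models, history = fs.meta_train(samples3, folds3, cfg, spec, seed=0,
                                    folds=[0])
    return models[0], history, spec
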