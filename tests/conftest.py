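"""Shared fixtures: small synthetic datasets with fully known truth."""

import numpy as np
import pytest

from colabel import LabeledDataset, SyntheticSpec, generate


@pytest.fixture
def small_dataset() -> LabeledDataset:
    """T = 40, n = 3, one group, seeded; labels from a logit truth."""
    spec = SyntheticSpec(
        n_binary=2,
        n_continuous=1,
        complement_pairs=False,
        true_alpha=[1.0, -1.5, 0.8, -0.2],
        group_sizes=(40,),
        seed=11,
    )
    dataset, _ = generate(spec)
    return dataset


@pytest.fixture
def two_group_dataset() -> LabeledDataset:
    spec = SyntheticSpec(
        n_binary=2,
        n_continuous=1,
        complement_pairs=False,
        true_alpha=[1.0, -1.0, 0.5, 0.0],
        group_sizes=(30, 25),
        seed=5,
    )
    dataset, _ = generate(spec)
    return dataset


@pytest.fixture
def noisy_dataset():
    """T = 600 with known class-conditional flips (0.10, 0.05)."""
    spec = SyntheticSpec(
        n_binary=3,
        n_continuous=1,
        complement_pairs=False,
        true_alpha=[1.5, -2.0, 1.0, 0.8, -0.6],
        flip=np.array([[0.90, 0.05], [0.10, 0.95]]),
        group_sizes=(600,),
        seed=7,
    )
    return generate(spec)
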