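"""Shared fixtures: small deterministic synthetic datasets."""

import numpy as np
import pytest

from gfpperm import EpochedDataset, NoiseModel, generate_null_epochs, split_labels


def make_dataset(
    C=4, S=6, K=10, n_a=4, seed=0, subject_id="sub-01", sampling_rate=128.0
) -> EpochedDataset:
    """One labelled subject of white-noise epochs."""
    rng = np.random.default_rng(seed)
    labels = np.full(K, "B", dtype="U1")
    labels[:n_a] = "A"
    rng.shuffle(labels)
    return EpochedDataset(
        subject_id=subject_id,
        data=rng.standard_normal((C, S, K)),
        labels=labels,
        times=np.arange(S) / sampling_rate - 0.01,
        sampling_rate=sampling_rate,
    )


@pytest.fixture
def dataset():
    return make_dataset()


@pytest.fixture
def miniature_group():
    """Four labelled subjects, 8 channels, 16 samples, 24 trials each."""
    noise = NoiseModel.equicorrelated(C=8, S=16, sd=12.0, rho=0.2)
    datasets = generate_null_epochs(noise, n_subjects=4, trials_per_subject=24, seed=11)
    rng = np.random.default_rng(12)
    return [
        ds.with_labels(split_labels(ds.n_trials, 1 / 3, rng=rng)) for ds in datasets
    ]
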