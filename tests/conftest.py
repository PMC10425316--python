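"""Shared fixtures: small synthetic panels generated at test time."""
import numpy as np
import pytest

from dasd import Dataset, SplitSpec, SyntheticSpec, generate, stratified_split


@pytest.fixture(scope="session")
def separable_small():
    """Well-separated two-class panel, no outliers: 60 samples x 6 features."""
    spec = SyntheticSpec(
        n_samples=60, class_sizes=(30, 30), n_informative=4, n_noise=2,
        effect_size=3.0, outlier_rate=0.0, seed=42,
    )
    ds, truth = generate(spec)
    return ds, truth


@pytest.fixture(scope="session")
def separable_split(separable_small):
    ds, _ = separable_small
    return stratified_split(ds, SplitSpec(0.5, 0.25, 0.25, seed=42))


@pytest.fixture(scope="session")
def default_panel():
    """The emulated cohort at its default shape (154 x 50, 10% outliers)."""
    spec = SyntheticSpec(seed=0)
    return generate(spec)


@pytest.fixture
def tiny_dataset():
    """Four hand-placed samples, two features, for exact-arithmetic checks."""
    return Dataset(
        values=np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [0.9, 0.9]]),
        labels=np.array([1, 1, 0, 0]),
        feature_names=["f0", "f1"],
        sample_ids=["a", "b", "c", "d"],
    )
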