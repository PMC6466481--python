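import numpy as np
import pytest
from hypothesis import settings

from wrhfs import ClassifierConfig, FeatureMeta, FeatureTable, SyntheticSpec, generate_synthetic_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_table():
    """8-sample, 3-feature table: f0 separates the classes, f2 is constant."""
    rng = np.random.default_rng(42)
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    f0 = np.where(labels == 1, 10.0, 0.0) + rng.normal(0, 0.1, 8)
    f1 = rng.normal(5, 1, 8)
    f2 = np.full(8, 3.3)
    return FeatureTable(
        np.column_stack([f0, f1, f2]),
        labels,
        [FeatureMeta("sep"), FeatureMeta("rand"), FeatureMeta("const")],
    )


@pytest.fixture
def planted_cohort():
    """Medium planted-signal cohort for wrapper/engine behaviour tests."""
    table, informative = generate_synthetic_cohort(
        SyntheticSpec(n_samples=300, n_informative=2, n_noise=4, effect_size=1.5, seed=7)
    )
    return table, informative


@pytest.fixture
def fast_config():
    """Small grid / few folds so SVM-backed tests stay quick."""
    return ClassifierConfig(penalty_grid=(1, 64), bandwidth_grid=(0.1, 1), cv_folds=3, seed=0)
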