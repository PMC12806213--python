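import numpy as np
import pytest

from pandaml import CohortSpec, generate_cohort
from pandaml.io import FeatureTable
from pandaml.preprocess import preprocess


def make_table(intensities, roles=None, batches=None, classes=None, **kw):
    """Small hand-built FeatureTable helper for unit tests."""
    X = np.asarray(intensities, dtype=float)
    n, p = X.shape
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(p)],
        intensities=X,
        batch=batches or ["b1"] * n,
        role=roles or ["biological"] * n,
        class_label=classes,
        **kw,
    )


@pytest.fixture(scope="session")
def separated_cohort():
    """Preprocessed two-class cohort with a strong injected class effect."""
    spec = CohortSpec(n_per_class={"HC": 60, "CRC": 60}, n_features=120,
                      n_informative=15, effect_size=2.0, n_batches=6,
                      missing_rate=0.02, seed=11)
    table, truth = generate_cohort(spec)
    clean, _ = preprocess(table)
    return clean, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Preprocessed two-class cohort with zero class effect."""
    spec = CohortSpec(n_per_class={"HC": 50, "CRC": 50}, n_features=80,
                      n_informative=10, effect_size=0.0, n_batches=5,
                      missing_rate=0.0, seed=12)
    table, _ = generate_cohort(spec)
    clean, _ = preprocess(table)
    return clean
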