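import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from permsig import SyntheticConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_planted():
    """80+24 samples, 40 features, 4 strong markers: fast pipeline fixture."""
    config = SyntheticConfig(
        n_pos=80, n_neg=24, n_features=40, n_informative=4, effect_size=2.5, seed=11
    )
    data, truth = generate(config)
    return data, truth


@pytest.fixture(scope="session")
def medium_planted():
    """Enough background features (120) for a well-determined score mixture;
    used by the full-pipeline stability tests."""
    config = SyntheticConfig(
        n_pos=80, n_neg=24, n_features=120, n_informative=5, effect_size=2.5, seed=11
    )
    data, truth = generate(config)
    return data, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """10 samples x 6 features, deterministic values, labels attached."""
    rng = np.random.default_rng(5)
    from permsig import LabeledDataset

    matrix = rng.normal(5.0, 1.0, size=(10, 6)).round(3)
    matrix[:5, 0] += 4.0  # feature f1 separates the classes
    return LabeledDataset(
        matrix=np.abs(matrix),
        feature_ids=[f"f{i}" for i in range(1, 7)],
        sample_ids=[f"s{i}" for i in range(1, 11)],
        labels=np.array(["tumor"] * 5 + ["normal"] * 5, dtype=object),
        positive_label="tumor",
    )
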