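import numpy as np
import pytest

from jointlasso import FusionSpec, split_by_group, standardize_subgroups


def make_grouped(seed=0, p=8, K=3, n_k=20, signal=True):
    """Random standardized grouped dataset with an optional linear signal."""
    rng = np.random.default_rng(seed)
    n = K * n_k
    X = rng.standard_normal((n, p))
    if signal:
        beta = rng.standard_normal(p) * (rng.random(p) < 0.5)
        y = X @ beta + rng.standard_normal(n)
    else:
        y = rng.standard_normal(n)
    labels = np.repeat([f"g{k}" for k in range(K)], n_k)
    return standardize_subgroups(split_by_group(X, y, labels))


@pytest.fixture
def small_ds():
    return make_grouped(seed=0, p=8, K=3, n_k=20)


@pytest.fixture
def two_group_ds():
    return make_grouped(seed=1, p=5, K=2, n_k=25)


@pytest.fixture
def spec():
    return FusionSpec(lam=0.2, gamma=0.5)


from hypothesis import HealthCheck, settings as _settings

_settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.differing_executors]
)
_settings.load_profile("default")
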