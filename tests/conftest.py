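import pytest
from hypothesis import HealthCheck, settings

import tomatoq as tq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def zero_noise_study():
    """Small panel with no replicate noise: quantification must round-trip."""
    config = tq.SyntheticConfig(
        seed=7, noise_cv=0.0, n_compounds=30, replicates=2, varieties_per_group=3
    )
    return tq.generate_study(config)


@pytest.fixture(scope="session")
def noisy_study():
    """Default study conditions (3 x 5 varieties, 3 replicates, 110 compounds)."""
    return tq.generate_study(tq.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def table2():
    """Packaged 34-compound OAV matrix with descriptors and group labels."""
    matrix, descriptors, groups = tq.table2_oav_matrix()
    return matrix, descriptors, groups


@pytest.fixture(scope="session")
def group_varieties(table2):
    _, _, groups = table2
    return {g: [v for v in groups.index if groups[v] == g] for g in groups.unique()}
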