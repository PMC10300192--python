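import numpy as np
import pytest

from glucodyn.datasets import Dataset, DesignSpec, NoiseSpec, TruthParams, generate_dataset
from glucodyn.model import GlobalParams


@pytest.fixture(scope="session")
def params() -> GlobalParams:
    return GlobalParams()


@pytest.fixture(scope="session")
def truth_noiseless() -> TruthParams:
    return TruthParams(noise=NoiseSpec(additive_sd=0.0))


@pytest.fixture(scope="session")
def truth_noisy() -> TruthParams:
    return TruthParams(noise=NoiseSpec(additive_sd=0.5))


@pytest.fixture(scope="session")
def tiny_spec_a() -> DesignSpec:
    # 2 seedings x 4 glucose x 1 replicate = 8 untreated wells
    return DesignSpec.dataset_a(
        seed=0, replicates=1, glucose_levels=(0.0, 1.0, 5.0, 10.0),
        seeding_levels={"low": 0.40, "high": 0.80},
    )


@pytest.fixture(scope="session")
def tiny_spec_b() -> DesignSpec:
    # 2 seedings x 3 glucose x 3 doses x 1 replicate = 18 wells
    return DesignSpec.dataset_b(
        seed=1, replicates=1, glucose_levels=(0.5, 2.0, 10.0),
        seeding_levels={"low": 0.40, "high": 0.80},
    )


@pytest.fixture(scope="session")
def tiny_a(tiny_spec_a, truth_noiseless) -> Dataset:
    return generate_dataset(tiny_spec_a, truth_noiseless, seed=11)


@pytest.fixture(scope="session")
def tiny_b(tiny_spec_b, truth_noiseless) -> Dataset:
    return generate_dataset(tiny_spec_b, truth_noiseless, seed=12)


@pytest.fixture(scope="session")
def small_combined(truth_noisy) -> Dataset:
    """Noisy A+B at 2 replicates: 60 + 90 wells for the ML harness."""
    a = generate_dataset(DesignSpec.dataset_a(seed=0, replicates=2), truth_noisy, seed=21)
    b = generate_dataset(DesignSpec.dataset_b(seed=1, replicates=2), truth_noisy, seed=22)
    return Dataset(wells=a.wells + b.wells, courses={**a.courses, **b.courses},
                   time_grid=a.time_grid, truth=truth_noisy,
                   true_kbys={**a.true_kbys, **b.true_kbys})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
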