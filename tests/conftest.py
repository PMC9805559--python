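import numpy as np
import pytest

import vaeda


@pytest.fixture(scope="session")
def small_dataset():
    """Compact multi-type dataset with injected doublets (fast pipeline runs)."""
    spec = vaeda.SyntheticSpec(n_singlets=300, n_genes=500, n_types=4, rng_seed=1)
    return vaeda.generate_dataset(spec)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic fixture (2,000 singlets, 5 types,
    10% doublets); shared across the end-to-end assertions."""
    data = vaeda.generate_dataset(vaeda.SyntheticSpec(rng_seed=1))
    result = vaeda.run_pipeline(data.counts, vaeda.PipelineConfig(seed=7))
    return data, result


@pytest.fixture(scope="session")
def two_blobs():
    """Two well-separated Gaussian blobs (100 points each, separation 20 SD)."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, size=(100, 20))
    b = rng.normal(20.0, 1.0, size=(100, 20))
    values = np.vstack([a, b])
    membership = np.repeat([0, 1], 100)
    return values, membership
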