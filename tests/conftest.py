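import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirdx.spectra_io import (
    Label,
    PrepClass,
    SpectraSet,
    SpectrumMeta,
    WavenumberGrid,
)
from nirdx.synthetic_data import SyntheticConfig, generate

settings.register_profile(
    "nirdx",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("nirdx")


def make_meta(n_samples: int, replicates: int = 1, label=Label.MUTANT):
    meta = []
    for s in range(n_samples):
        for r in range(1, replicates + 1):
            meta.append(
                SpectrumMeta(
                    sample_id=f"S{s + 1:03d}",
                    replicate=r,
                    prep_class=PrepClass.PARAFFIN_EMBEDDED,
                    label=label if not callable(label) else label(s),
                )
            )
    return meta


@pytest.fixture
def tiny_grid():
    return WavenumberGrid(np.array([9000.0, 8000.0, 6600.0, 6000.0, 4000.0]))


@pytest.fixture
def tiny_set(tiny_grid):
    absorbance = np.array(
        [
            [0.1, 0.2, 0.3, 0.4, 0.5],
            [0.5, 0.4, 0.3, 0.2, 0.1],
        ]
    )
    meta = [
        SpectrumMeta("S001", 1, PrepClass.PARAFFIN_EMBEDDED, Label.MUTANT),
        SpectrumMeta("S002", 1, PrepClass.PARAFFIN_EMBEDDED, Label.WILD_TYPE),
    ]
    return SpectraSet(tiny_grid, absorbance, meta)


@pytest.fixture(scope="session")
def default_data():
    """One frozen-default synthetic dataset (seed 1), shared across tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def separable_clusters():
    """Two well-separated 2-D clusters: centers (0,0) and (10,10), sd 0.1."""
    rng = np.random.default_rng(7)
    a = rng.normal((0.0, 0.0), 0.1, size=(20, 2))
    b = rng.normal((10.0, 10.0), 0.1, size=(20, 2))
    scores = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    return scores, labels
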