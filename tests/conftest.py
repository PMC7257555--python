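import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_reference():
    """Nine homopolymer loci (12 bp tracts) on one synthetic contig."""
    from msical import make_reference

    reference, catalog = make_reference(9, 12, seed=3)
    return reference, catalog


@pytest.fixture(scope="session")
def paired_reads(toy_reference):
    """Tumor (purity 0.5, first 3 loci shifted -3) and normal read sets."""
    from msical.simulate import simulate_sample, truth_from_catalog

    reference, catalog = toy_reference
    unstable = [l.key for l in catalog[:3]]
    truth_t = truth_from_catalog(catalog, 0.5, unstable, -3, coverage=60, seed=7)
    truth_n = truth_from_catalog(catalog, 0.0, (), 0, coverage=60, seed=8)
    tumor = simulate_sample(truth_t, reference, sample_tag="T")
    normal = simulate_sample(truth_n, reference, sample_tag="N")
    return tumor, normal, unstable


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
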