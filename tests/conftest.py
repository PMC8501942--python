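import pytest

from planktonmap import critical_step, interior_equilibrium, load_fixture


@pytest.fixture(scope="session")
def bloom():
    """Benchmark bloom parameter set (step size 0.3, sink regime)."""
    return load_fixture("ns_bloom").params


@pytest.fixture(scope="session")
def mild():
    """Mild-toxicity parameter set: interior sink, no Dt(h)=1 crossing."""
    return load_fixture("consistency_stable").params


@pytest.fixture(scope="session")
def bloom_interior(bloom):
    point, residuals, unique, _ = interior_equilibrium(bloom)
    assert point is not None and unique
    return point


@pytest.fixture(scope="session")
def bloom_hstar(bloom):
    return critical_step(bloom)
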