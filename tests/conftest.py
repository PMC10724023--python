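import pytest

import germload as gl


@pytest.fixture(scope="session")
def cfg():
    return gl.RunConfig(seed=11)


@pytest.fixture(scope="session")
def small_collection():
    """A quick 12-sample collection for I/O and classification tests."""
    return gl.simulate_collection(
        gl.SimSpec(n_samples=12, n_variants=300, frac_deleterious=0.1, seed=7)
    )


@pytest.fixture(scope="session")
def default_collection():
    """The genebank-like default: 70 selfing samples, 5000 variants."""
    return gl.simulate_collection(gl.SimSpec(seed=11))
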