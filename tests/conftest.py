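import pytest

from circrpl.synthetic_data import SimParams, simulate_world


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A moderate synthetic world shared by read-only tests."""
    params = SimParams(seed=42, n_genes=120, n_circ=200)
    return simulate_world(params, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """A world with perfect detectors (no dropout, no jitter)."""
    params = SimParams(
        seed=43, n_genes=120, n_circ=200, detector_dropout=0.0, coord_jitter=0.0
    )
    return simulate_world(params, tmp_path_factory.mktemp("clean_bundle"))
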