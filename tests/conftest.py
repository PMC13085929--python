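import pytest

from matmine.pipeline import run_pipeline
from matmine.simulate import generate_strain_set

SEED = 11


@pytest.fixture(scope="session")
def strain_set():
    """The four-strain reference design at test scale, fixed seed."""
    return generate_strain_set(seed=SEED)


@pytest.fixture(scope="session")
def pipeline_result(strain_set):
    """Full pipeline output over the reference strain set (computed once)."""
    strains, _ = strain_set
    return run_pipeline(strains)
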