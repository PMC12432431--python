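import pytest

from thermoidp.forcefield import load_forcefield


@pytest.fixture(scope="session")
def ff():
    """Bundled model-3 force field with synthetic default parameters."""
    return load_forcefield(model=3)
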