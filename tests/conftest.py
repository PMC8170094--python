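import pytest

from bc1sox.thermo import Thermo


@pytest.fixture(scope="session")
def thermo300() -> Thermo:
    """Thermal state at 300 K (kBT = 0.59616 kcal/mol)."""
    return Thermo(300.0)
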