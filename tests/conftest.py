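import pytest

from needleox import ExtinctionTable, MeasurementGeometry


@pytest.fixture(scope="session")
def table() -> ExtinctionTable:
    """The shipped hemoglobin extinction table."""
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def geom() -> MeasurementGeometry:
    """Nominal needle-tip geometry: L = 1 cm, B(lambda) = 1."""
    return MeasurementGeometry()
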