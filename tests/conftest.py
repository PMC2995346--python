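import pytest

from twostroke.energy import bank_for_k
from twostroke.fitting import CurveLibrary
from twostroke.stimulus import SamplingGrid


@pytest.fixture(scope="session")
def grid():
    return SamplingGrid()


@pytest.fixture(scope="session")
def bank110():
    """Sensor bank at k=110, the photopic best-fit scale factor."""
    return bank_for_k(110.0)


@pytest.fixture(scope="session")
def curves():
    """Session-wide memoised model curves; shared so each (task, k) curve
    is computed once across the whole suite."""
    return CurveLibrary()
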