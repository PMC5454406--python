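import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tipirt.fold import EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel()
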