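import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fps import doseresponse, fixtures


@pytest.fixture(scope="session")
def ir_table():
    return doseresponse.load_ir_table()


@pytest.fixture(scope="session")
def bridge_structure():
    return fixtures.synth_toy_structure(fixtures.bridge_plan())


@pytest.fixture(scope="session")
def hub_structure():
    return fixtures.synth_toy_structure(fixtures.hub_plan(6))


@pytest.fixture(scope="session")
def contact_structure():
    return fixtures.synth_toy_structure(fixtures.contact_plan())


@pytest.fixture(scope="session")
def three_residue_structure():
    return fixtures.synth_toy_structure(fixtures.three_residue_plan())
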