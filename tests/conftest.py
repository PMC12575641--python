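import pytest

from gbmgermline.fixtures import panel_fixture, table1_fixture
from gbmgermline.phenotypes import toy_signature_matrix
from gbmgermline.pipeline import run_table1


@pytest.fixture(scope="session")
def panel():
    return panel_fixture()


@pytest.fixture(scope="session")
def fixture():
    return table1_fixture()


@pytest.fixture(scope="session")
def toy_matrix():
    return toy_signature_matrix()


@pytest.fixture(scope="session")
def table1_run():
    """Full pipeline run over the packaged evidence-table fixture."""
    return run_table1()
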