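import pytest

from mirstage import builtin_panels, run_stage
from mirstage.enums import STAGE_ORDER
from mirstage.fixtures import (
    load_fixture_directions,
    load_fixture_edges,
    load_literature_update,
)


@pytest.fixture(scope="session")
def edges_table():
    return load_fixture_edges()


@pytest.fixture(scope="session")
def directions_db():
    return load_fixture_directions()


@pytest.fixture(scope="session")
def literature_db():
    return load_literature_update()


@pytest.fixture(scope="session")
def panels():
    return builtin_panels()


@pytest.fixture(scope="session")
def stage_results(edges_table, directions_db, panels):
    return [run_stage(s, panels, edges_table, directions_db) for s in STAGE_ORDER]
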