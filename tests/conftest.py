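import pytest

from immunoscreen.config import config_for_fixture
from immunoscreen.fixtures import paper_core_fixture
from immunoscreen.pipeline import run_pipeline


@pytest.fixture(scope="session")
def core_fixture(tmp_path_factory):
    """The worked-example fixture directory plus its ground-truth manifest."""
    d = tmp_path_factory.mktemp("core_fixture")
    manifest = paper_core_fixture(d)
    return d, manifest


@pytest.fixture(scope="session")
def core_result(core_fixture, tmp_path_factory):
    """A full pipeline run over the worked-example fixture."""
    d, manifest = core_fixture
    out = tmp_path_factory.mktemp("core_out")
    result = run_pipeline(config_for_fixture(d, out))
    return result, manifest
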