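import pytest

from cannatype.datasets import load_reference_panel, reference_records
from cannatype.synthetic import PanelConfig, make_panel, make_reference_fixtures


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged 85-sample survey table."""
    return load_reference_panel()


@pytest.fixture(scope="session")
def reference_cannabinoids():
    return reference_records()


@pytest.fixture(scope="session")
def fixture_refs():
    """(sequences, assay) engineered to the nominal band sizes."""
    return make_reference_fixtures()


@pytest.fixture(scope="session")
def small_panel_config():
    return PanelConfig(seed=7, n_drug=4, n_intermediate=3, n_fiber=3)


@pytest.fixture(scope="session")
def small_panel(small_panel_config):
    """A 10-sample panel for sequence-level tests."""
    return make_panel(small_panel_config)


@pytest.fixture(scope="session")
def default_panel():
    """The survey-sized 70/11/4 synthetic panel."""
    return make_panel(PanelConfig(seed=1))
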