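import warnings

import pytest

from isowue.constants import DEFAULT_CONSTANTS
from isowue.physio import compute_iwue_table
from isowue.synthetic import TransectConfig, generate_transect


@pytest.fixture(scope="session")
def default_transect():
    """Default-condition synthetic transect (seed 1) with ground truth."""
    table, truth = generate_transect(TransectConfig(seed=1))
    return table, truth


@pytest.fixture(scope="session")
def iwue_table(default_transect):
    """The default transect pushed through the analysis chain."""
    table, _ = default_transect
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_iwue_table(table)


@pytest.fixture(scope="session")
def small_transect():
    """A small, fast transect (20 sites) for pipeline/CLI tests."""
    cfg = TransectConfig(seed=5, n_sites=20)
    table, truth = generate_transect(cfg)
    return cfg, table, truth


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS
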