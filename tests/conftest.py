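import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("reefbudget", derandomize=True, database=None)
hypothesis_settings.load_profile("reefbudget")

from reefbudget.io_config import default_rate_library
from reefbudget.synthetic_data import SynthConfig


@pytest.fixture(scope="session")
def rates():
    return default_rate_library()


@pytest.fixture
def small_cfg():
    """A trimmed synthetic study for fast I/O and round-trip tests."""
    return SynthConfig(
        seed=11,
        n_sites_per_gulf=2,
        n_transects=2,
        n_corals_per_site=4,
        tide_n_years=10,
    )


@pytest.fixture
def default_cfg():
    """The full-size synthetic study (3 sites x 6 transects x 5 periods)."""
    return SynthConfig(seed=7)
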