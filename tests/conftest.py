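import numpy as np
import pytest

from agscore import default_panel, default_simulation_config, simulate_cohort
from agscore.panel import GenotypeProfile


@pytest.fixture(scope="session")
def panel_smap():
    return default_panel()


@pytest.fixture(scope="session")
def panel(panel_smap):
    return panel_smap[0]


@pytest.fixture(scope="session")
def smap(panel_smap):
    return panel_smap[1]


@pytest.fixture(scope="session")
def make_profile(panel_smap):
    """Build a GenotypeProfile from a tuple of per-marker scores (GS order
    follows the panel order)."""
    panel, smap = panel_smap

    def _make(gs_tuple):
        return GenotypeProfile(
            {p.key: smap.genotype_for_score(p.key, g) for p, g in zip(panel, gs_tuple)}
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject cohort drawn from the default per-group frequencies."""
    cfg = default_simulation_config()
    cfg.group_sizes = {"low": 8, "medium": 15, "high": 7}
    return simulate_cohort(cfg, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20100618)
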