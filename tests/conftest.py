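import warnings

import pytest

from ogpeel.core_io import SpeciesPanel
from ogpeel.simfam import SimConfig, simulate_family


@pytest.fixture(scope="session")
def panel() -> SpeciesPanel:
    return SpeciesPanel.default()


@pytest.fixture(scope="session")
def small_sim():
    """A compact deterministic family: 3 clusters, 6 OGs, 9 species."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_family(SimConfig(seed=42))


@pytest.fixture(scope="session")
def noevent_sim():
    """No duplication/loss: exactly one gene per species per ancestral OG."""
    cfg = SimConfig(
        n_ancestral_ogs=3, n_clusters=3, dup_rate=0.0, loss_rate=0.0,
        intron_gain_prob=0.0, intron_loss_prob=0.0,
        pseudogene_prob=0.0, truncated_prob=0.0, seed=7,
    )
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """Homogeneous duplication rates: clean planted divergent clusters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_family(SimConfig(seed=42, og_rate_variation=False, dup_rate=0.6))
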