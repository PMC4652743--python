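import numpy as np
import pytest

import emulsim as es
from emulsim.abundance_stats import gate_and_normalize
from emulsim.fragment_io import assign_targets, collapse_to_matrix, default_target_map


@pytest.fixture(scope="session")
def target_map():
    return default_target_map()


def simulate_gated(cfg, sample_days, tmap=None):
    """Run the generator and return (gated matrix, ground truth)."""
    tmap = tmap or default_target_map()
    peaks, truth = es.simulate_experiment(cfg, tmap, sample_days)
    annotated = assign_targets(peaks.drop(columns=["target"]), tmap)
    return gate_and_normalize(collapse_to_matrix(annotated)), truth


@pytest.fixture(scope="session")
def control_day12():
    """A control-condition run sampled on days 1 and 2 (~340 gated colonies)."""
    cfg = es.SimConfig(seed=20, n_droplets=3600, days=2)
    return simulate_gated(cfg, [1, 2])


@pytest.fixture(scope="session")
def curcumin_day12():
    """A curcumin-treated run sampled on days 1 and 2."""
    cfg = es.SimConfig(seed=20, n_droplets=3600, days=2,
                       curcumin=es.CurcuminConfig(enabled=True))
    return simulate_gated(cfg, [1, 2])


@pytest.fixture(scope="session")
def null_dips_100():
    """Shared Uniform(0,1) dip null for n=100 (B=2000)."""
    return es.dip_null_distribution(100, 2000, np.random.default_rng(987))
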