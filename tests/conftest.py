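import matplotlib
matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from zrskit.imaging import quantify_bundle
from zrskit.synthetic import (SimulationConfig, annotation_from_truth,
                              simulate_limb_bundle, simulate_pbm_table)

CONSENSUS = "CAGATGGC"


@pytest.fixture(scope="session")
def clean_table():
    """Noise-free synthetic PBM table: geometric decay 0.5 per mismatch."""
    return simulate_pbm_table(CONSENSUS, optimal_intensity=40_000.0,
                              decay_per_mismatch=0.5, noise_cv=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """One simulated embryo with zero noise, plus its ground truth."""
    cfg = SimulationConfig.default(96, 80, noise_sd=0.0, seed=11)
    return simulate_limb_bundle(cfg)


@pytest.fixture(scope="session")
def noiseless_record(noiseless_bundle):
    bundle, truth = noiseless_bundle
    return quantify_bundle(bundle, annotation_from_truth(truth), "posterior")


def small_config(**overrides) -> SimulationConfig:
    """Compact frame used throughout the suite to keep simulations fast."""
    return SimulationConfig.default(96, 80, **overrides)
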