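import numpy as np
import pandas as pd
import pytest

from tidalcarbon import SimScenario, SoilCore, simulate_accretion, simulate_core


def make_core(core_id="T1", n=10, loi=None, dbd=None, collection_year=2015, **cols):
    """Small hand-built core for unit tests."""
    data = pd.DataFrame({"depth_min": np.arange(n, dtype=float),
                         "depth_max": np.arange(1, n + 1, dtype=float)})
    if loi is not None:
        data["loi"] = loi
    if dbd is not None:
        data["dry_bulk_density"] = dbd
    for k, v in cols.items():
        data[k] = v
    return SoilCore(core_id=core_id, data=data, collection_year=collection_year)


@pytest.fixture(scope="session")
def default_scenario():
    return SimScenario(seed=3, n_cores=1)


@pytest.fixture(scope="session")
def sim_core(default_scenario):
    """One default-scenario simulated core with its truth record."""
    rng = np.random.default_rng(3)
    ages = simulate_accretion(default_scenario, rng)
    core, truth = simulate_core(default_scenario, ages, core_id="SIM-01", rng=rng)
    return core, truth, ages


@pytest.fixture(scope="session")
def quiet_core():
    """Near-noise-free simulated core (oracle-equivalence conditions)."""
    sc = SimScenario(seed=21, n_cores=1, counting_cv=0.01, sd_floor=0.05,
                     om_noise_sd=1e-4, dbd_noise_cv=1e-4)
    rng = np.random.default_rng(21)
    ages = simulate_accretion(sc, rng)
    core, truth = simulate_core(sc, ages, core_id="QUIET", rng=rng)
    return core, truth, ages
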