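import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from heartphase import prepare_windows
from heartphase import simulate as sim
from heartphase.model import GapSeries


@pytest.fixture(scope="session")
def small_sim():
    """Four regular days at cohort-central parameters."""
    cfg = sim.SimConfig(n_days=4, seed=11)
    return sim.simulate_records(cfg)


@pytest.fixture(scope="session")
def small_windows(small_sim):
    binned, sleeps, days, windows = prepare_windows(small_sim.records)
    assert windows, "fixture must yield at least one fit window"
    return binned, sleeps, days, windows


@pytest.fixture(scope="session")
def prc_recovery_run():
    """102-day entrained dynamic-clock simulation (PRC recovery oracle)."""
    cfg = sim.prc_recovery_config(n_days=102, seed=50)
    res = sim.simulate_records(cfg)
    binned, sleeps, days, windows = prepare_windows(res.records)
    track = sim.track_from_ledger(res.ledger, res.sleep_intervals)
    return res, binned, track


def random_gap_series(rng, n=None):
    """Arbitrary gappy observation series on the 5-min grid."""
    n = n or rng.integers(5, 50)
    gaps = rng.integers(1, 30, size=n - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps) / 12.0]) + rng.uniform(0, 24)
    y = rng.normal(70, 10, size=n)
    x = rng.gamma(1.0, 8.0, size=n)
    return GapSeries(t, y, x)
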