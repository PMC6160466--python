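import numpy as np
import pandas as pd
import pytest

from reinrhythm import simulate


@pytest.fixture(scope="session")
def qc_sim():
    """60-day single-animal deployment with default artifact rates."""
    cfg = simulate.default_paper_config(seed=11)
    cfg.individuals = 1
    cfg.start, cfg.end = "2012-11-15", "2013-01-14"
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def year_sim():
    """Full study year (Nov 15 - Nov 15), one animal, activity channel only."""
    cfg = simulate.default_paper_config(seed=21)
    cfg.individuals = 1
    return simulate.generate(cfg, channels=("activity",))


@pytest.fixture(scope="session")
def grid_3min():
    """15 days of 3-minute timestamps."""
    return pd.date_range("2013-02-01", periods=7200, freq="180s")


def make_series(ts, values, channel="activity", ind="x"):
    from reinrhythm.core import TelemetrySeries

    return TelemetrySeries(channel, ts, np.asarray(values, dtype=float), individual_id=ind)
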