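import numpy as np
import pytest

from ira.core_io import PairedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20130501)


@pytest.fixture
def fixed_pairs_20():
    """Deterministic 20-point dataset with a mid-series step, used wherever a
    fixed small regression problem is needed (e.g. cross-validation oracles)."""
    rng = np.random.default_rng(42)
    years = np.arange(1991, 2011)
    x = np.round(rng.normal(0.0, 0.3, 20) + np.where(years >= 2001, 0.25, 0.0), 6)
    y = np.round(
        np.where(years <= 2000, 1.0, -1.0) - 0.8 * x + rng.normal(0, 0.25, 20), 6
    )
    return PairedSeries(years=years, x=x, y=y, lag=0)
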