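import numpy as np
import pandas as pd
import pytest

from ch4hyst import analyze_dataset
from ch4hyst.datamodel import DailySeries, SiteMeta
from ch4hyst import synthetic as syn


def make_series(site_id="TST", ecosystem_type="fen", latitude=55.0, **columns):
    """Build a DailySeries from keyword column arrays (dates auto-generated)."""
    n = max(len(v) for v in columns.values())
    idx = pd.date_range("2015-01-01", periods=n, freq="D")
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()}, index=idx)
    meta = SiteMeta(site_id, ecosystem_type, latitude, 0.0)
    return DailySeries(site_id=site_id, data=df, meta=meta)


@pytest.fixture(scope="session")
def small_network():
    """A seeded 12-site synthetic network with 20% flux noise."""
    return syn.gen_network(n_sites=12, seed=5, flux_noise_cv=0.2)


@pytest.fixture(scope="session")
def analyzed_network(small_network):
    """Results + day table of the small network's full hysteresis analysis."""
    results, day_table, skipped = analyze_dataset(small_network.dataset)
    return {
        "net": small_network,
        "results": results,
        "day_table": day_table,
        "skipped": skipped,
    }
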