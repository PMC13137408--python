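import numpy as np
import pandas as pd
import pytest

from ebcflux import synthetic
from ebcflux.core import FluxTable


@pytest.fixture(scope="session")
def site_meta():
    return synthetic.default_site_meta()


@pytest.fixture(scope="session")
def clean_year(site_meta):
    """One noise-free, gap-free year with imposed closure f = 0.8."""
    table, truth = synthetic.generate_site(
        site_meta, synthetic.TruthRecord(closure_fraction=0.8, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def noisy_year(site_meta):
    """A realistic year: f = 0.85, 10 % multiplicative flux noise, 10 %
    gaps, nocturnal low-u* suppression."""
    truth = synthetic.TruthRecord(closure_fraction=0.85, noise_mult=0.10,
                                  gap_fraction=0.10, ustar_threshold=0.25,
                                  seed=42)
    table, truth = synthetic.generate_site(site_meta, truth)
    return table, truth


@pytest.fixture()
def two_day_table(site_meta):
    table, _ = synthetic.generate_site(
        site_meta, synthetic.TruthRecord(closure_fraction=0.9, seed=3),
        start="2023-06-01", days=2)
    return table


def make_table(values: dict, start="2023-06-01", n=None, profiles=None) -> FluxTable:
    """Small hand-built flux table for targeted tests."""
    if n is None:
        n = next(len(v) for v in values.values() if not np.isscalar(v))
    idx = pd.date_range(pd.Timestamp(start) + pd.Timedelta(minutes=30),
                        periods=n, freq="30min", name="TIMESTAMP_END")
    data = {k: (np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, float))
            for k, v in values.items()}
    return FluxTable(pd.DataFrame(data, index=idx), profiles or {})
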