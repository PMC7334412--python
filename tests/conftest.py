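import numpy as np
import pandas as pd
import pytest

from nkgate.events import EventTable
from nkgate.panel import default_panel
from nkgate.pipeline import run_analysis
from nkgate.populations import DonorConfig, hd_population_specs
from nkgate.simulate import sample_donor
from nkgate.thresholds import estimate_table_thresholds


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def hd_specs():
    return hd_population_specs()


@pytest.fixture(scope="session")
def small_donor(hd_specs, panel):
    """One 20k-event healthy donor, no abundance jitter (fast, deterministic)."""
    dc = DonorConfig("unit_hd", seed=7, n_events=20_000, abundance_jitter=None)
    return sample_donor(dc, hd_specs, panel)


@pytest.fixture(scope="session")
def small_model(small_donor):
    return estimate_table_thresholds(small_donor)


@pytest.fixture(scope="session")
def full_analysis():
    """The default study: 20 donors x 50,000 events per condition, master seed 42."""
    return run_analysis(conditions=("HD", "HIV_untreated", "HIV_cART", "MM"),
                        n_donors=20, n_events=50_000, seed=42)


def tiny_table(values: dict[str, list[float]], panel) -> EventTable:
    """Hand-written event table; markers not listed default to raw 0."""
    n = len(next(iter(values.values())))
    data = {}
    for ch in panel:
        data[ch.channel_id] = np.asarray(values.get(ch.marker, [0.0] * n), dtype=float)
    return EventTable(pd.DataFrame(data), panel)
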