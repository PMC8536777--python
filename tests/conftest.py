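import numpy as np
import pandas as pd
import pytest

from chronode import SimDesign, simulate_experiment, TimeSeriesCounts
from chronode.simdata import SeriesSpec, KineticSpec

HOURLY = tuple(float(t) for t in range(22))


@pytest.fixture(scope="session")
def hourly_grid():
    return np.asarray(HOURLY)


@pytest.fixture(scope="session")
def two_condition_layout():
    """One transected and one uninjured series, hourly over 0-21 h."""
    return [SeriesSpec("T1", "transected", HOURLY),
            SeriesSpec("U1", "uninjured", HOURLY)]


@pytest.fixture(scope="session")
def small_experiment(two_condition_layout):
    """120 genes, one planted module of 30, the rest null; no batch effect."""
    spec = KineticSpec("intermediate", "up", False, onset_time=2.5,
                       peak_time=5.0, amplitude=2.0)
    design = SimDesign(n_genes=120, module_specs=[(30, spec)],
                       conditions=("transected", "uninjured"),
                       series_layout=two_condition_layout,
                       batch_sd=0.0, seed=42)
    return simulate_experiment(design)


@pytest.fixture()
def toy_counts():
    """3 genes x 4 samples toy container with full metadata."""
    meta = pd.DataFrame({
        "condition": ["transected", "transected", "uninjured", "uninjured"],
        "series": ["T1", "T1", "U1", "U1"],
        "time_hpt": [0.0, 1.0, 0.0, 1.0],
        "batch": ["T1", "T1", "U1", "U1"],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    counts = pd.DataFrame([[10, 12, 9, 11], [0, 5, 0, 6], [100, 90, 110, 95]],
                          index=["gA", "gB", "gC"], columns=meta.index)
    return TimeSeriesCounts(counts=counts, meta=meta)
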