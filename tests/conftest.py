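import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sulfurscape as ss

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """The synthetic landscape at study-condition defaults."""
    return ss.world.make_world()


@pytest.fixture(scope="session")
def sampled_world(default_world):
    sites, samples, registry = ss.world.sample_world(default_world)
    return default_world, sites, samples, registry


@pytest.fixture(scope="session")
def screened_matrix(sampled_world):
    """QC-screened, fence-cleaned regression matrix from the default world."""
    world, sites, samples, _ = sampled_world
    retained, _ = ss.samples.qc_screen(samples, purpose="isoscape")
    keep = []
    for _, grp in retained.groupby("region_class"):
        flags = ss.assign.detect_nonlocals(grp)
        keep += list(flags.loc[flags["flag"] == "local", "sample_id"])
    local = retained[retained["sample_id"].isin(keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = ss.rasters.build_matrix(local, sites, world.stack)
    return matrix


@pytest.fixture(scope="session")
def fitted_forest(screened_matrix):
    preds = [c for c in screened_matrix.columns if c.startswith("r.")]
    est = ss.isoscape.IsoscapeForest(n_trees=200, seed=11)
    est.fit(screened_matrix[preds], screened_matrix["d34S"])
    return est


@pytest.fixture()
def tiny_samples():
    """A hand-written 3-row sample table (all QC metrics inside windows)."""
    return pd.DataFrame({
        "sample_id": ["a", "b", "c"],
        "site_id": ["s1", "s1", "s2"],
        "kind": ["human", "human", "animal"],
        "taxon": ["Homo sapiens"] * 2 + ["Ovis/Capra"],
        "period": ["Chalcolithic"] * 3,
        "d13C": [-19.5, -20.1, -20.8],
        "d15N": [9.1, 8.7, 5.2],
        "d34S": [13.2, 12.8, 14.0],
        "pct_col": [2.0, 3.1, 4.0],
        "pct_C": [35.0, 40.0, 42.0],
        "pct_N": [12.0, 14.5, 15.0],
        "pct_S": [0.2, 0.25, 0.22],
        "cn_ratio": [3.2, np.nan, np.nan],
        "cs_ratio": [550.0, np.nan, np.nan],
        "ns_ratio": [180.0, np.nan, np.nan],
        "local_status": ["local", "unknown", "unknown"],
        "source": ["this_study"] * 3,
    })
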