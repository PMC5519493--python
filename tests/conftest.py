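import numpy as np
import pandas as pd
import pytest

from interdigitate import (
    GeneratorParams,
    SessionTimeseries,
    build_icosphere,
    plant_networks,
    simulate_study,
)


@pytest.fixture(scope="session")
def mesh2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def template3(mesh3):
    """Two interdigitated networks across six zones, no jitter."""
    return plant_networks(mesh3, n_networks=2, n_zones=6, parcel_radius=2,
                          jitter_steps=0, subject_seed=0)


@pytest.fixture(scope="session")
def small_study():
    """One subject, 8 runs x 200 frames at level 3 (desk-scale default)."""
    params = GeneratorParams(subdivision_level=3, n_subjects=1, n_sessions=8,
                             frames_per_run=200, master_seed=11)
    return simulate_study(params)


def make_ts(data, tr=1.0, nuisance=None, run_id=2, subject_id=0):
    """Bare session (replication run id by default) from a data matrix."""
    nuis = nuisance if nuisance is not None else pd.DataFrame(index=range(np.asarray(data).shape[1]))
    return SessionTimeseries(data=np.asarray(data, dtype=float), tr_seconds=tr,
                             nuisance=nuis, run_id=run_id, subject_id=subject_id)
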