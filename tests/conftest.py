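import numpy as np
import pytest

from radphantom import phantom
from radphantom.datasets import (
    load_ct_distance_table,
    load_system_errors,
)
from radphantom.projection import AcquisitionGeometry


@pytest.fixture(scope="session")
def errors_df():
    return load_system_errors()


@pytest.fixture(scope="session")
def errors_by_system(errors_df):
    return {s: g.error_mm.to_numpy()
            for s, g in errors_df.groupby("system", sort=False)}


@pytest.fixture(scope="session")
def errors_by_method(errors_df):
    return {m: g.error_mm.to_numpy()
            for m, g in errors_df.groupby("method", sort=False)}


@pytest.fixture(scope="session")
def ct_table():
    return load_ct_distance_table()


@pytest.fixture(scope="session")
def layout(ct_table):
    return phantom.reconstruct_layout(ct_table)


@pytest.fixture(scope="session")
def slot_geometry():
    return AcquisitionGeometry.from_preset("Eagle Eye", downsample=4.0)


@pytest.fixture(scope="session")
def one_shot_geometry():
    return AcquisitionGeometry.from_preset("DSI-DRP", downsample=4.0)


@pytest.fixture(scope="session")
def rotational_geometry():
    return AcquisitionGeometry.from_preset("GC85A", downsample=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
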