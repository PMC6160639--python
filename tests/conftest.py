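import numpy as np
import pandas as pd
import pytest

from execsim.core import AcquisitionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def att_acq():
    return AcquisitionSpec.attention()


@pytest.fixture
def nb_acq():
    return AcquisitionSpec.nback()


@pytest.fixture
def small_acq():
    """A tiny grid for fast volume-level tests."""
    return AcquisitionSpec(
        n_volumes=40, n_dummy=2, grid_shape=(8, 8, 8), voxel_size_mm=(3.0, 3.0, 3.0)
    )


def make_events(rows):
    """Helper to build a minimal valid event table from dicts."""
    defaults = dict(
        onset=0.0,
        duration=1.0,
        task="attention",
        condition="divided_attention",
        modality="both",
        switch="n/a",
        congruent=True,
        block="b0",
        correct=None,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])
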