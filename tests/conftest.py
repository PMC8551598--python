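import numpy as np
import pytest

from behconn import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-scale cohort spec: 4 x 15 subjects, 40 regions, short scans."""
    return synth.default_spec(n_per_group=15, n_regions=40, n_timepoints=120)


@pytest.fixture
def tiny_cohort(small_spec):
    return synth.gen_timeseries_cohort(small_spec, seed=7)
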