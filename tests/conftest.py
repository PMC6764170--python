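import numpy as np
import pytest

import vfforecast as vf
from vfforecast.pipeline import extract_features

COHORT_SEED = 101


@pytest.fixture(scope="session")
def table2_cohort():
    """One full-size two-group cohort under the default study conditions."""
    return vf.generate_cohort(27, 28, *vf.preset_params("table2"),
                              seed=COHORT_SEED)


@pytest.fixture(scope="session")
def table2_features(table2_cohort):
    table, excluded = extract_features([c.record for c in table2_cohort])
    assert not excluded
    return table


@pytest.fixture()
def clean_record():
    """A noise-free, unmodulated synthetic record at 250 Hz."""
    params = vf.GroupParams(mean_rr=800, lf_mod_amp=0, hf_mod_amp=0,
                            rr_noise_sd=0, r_amp_base=1000,
                            r_amp_mod_depth=0, area_jitter_sd=0,
                            ecg_noise_sd=0)
    record, truth = vf.generate_record(params, duration=30, fs=250, seed=7)
    return record, truth


def make_rr(values):
    values = np.asarray(values, dtype=float)
    t = np.cumsum(values) / 1000.0
    return vf.RRSeries(rr=values, t=t)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
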