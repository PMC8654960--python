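import numpy as np
import pytest

import vitalembed as ve


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six short stays, three signals, fully deterministic."""
    profile = ve.small_profile(name="OR0", n_stays=6, seed=7,
                               stay_length_range=(80, 110))
    records, report = ve.simulate_cohort(profile)
    return profile, records, report


@pytest.fixture(scope="session")
def labeled_windows(tiny_cohort):
    _, records, _ = tiny_cohort
    windows = ve.build_window_set(records)
    labels = ve.label_cohort(windows, ve.get_outcome("hypoxemia"))
    return windows, labels


def make_record(signals, variables, stay_id="s0", mask=None, **static):
    signals = np.asarray(signals, dtype=float)
    if mask is None:
        mask = ~np.isnan(signals)
    defaults = dict(height=170.0, weight=80.0, asa_code=2.0,
                    asa_emergency=0.0, gender=1.0, age=50.0)
    defaults.update(static)
    return ve.StayRecord(
        stay_id=stay_id,
        static=ve.StaticVector(**defaults),
        signals=signals,
        mask=mask,
        hospital_tag="T",
        variables=tuple(variables),
    )
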