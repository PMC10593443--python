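import numpy as np
import pandas as pd
import pytest

from metscreen import ParticipantRecord, default_cohort_config, sample_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230942)


@pytest.fixture()
def record():
    """A mid-range male record used across example-based tests."""
    return ParticipantRecord(
        id="p1", sex="male", age=40, height=170, weight=75, wc=94, nc=38,
        muac=31, sbp=120, dbp=78, fbg=92, tg=1.7, hdl=1.31,
    )


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A seeded 500-subject synthetic cohort shared by pipeline tests."""
    cfg = default_cohort_config(n=500, seed=11)
    return sample_cohort(cfg)
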