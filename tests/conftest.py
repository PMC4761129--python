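import numpy as np
import pytest

from gaitspc import DailyRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def records_from_medians(medians, n_i=1, start_day=1):
    """Series of daily records, one synthetic measurement repeated n_i times
    per day so the day's median equals the given value."""
    out = []
    for i, m in enumerate(medians):
        out.append(DailyRecord(day=start_day + i, times=(float(m),) * n_i))
    return out


@pytest.fixture
def flat_series():
    """30 constant days at 5 s: an in-control series with zero dispersion in
    the medians but nonzero pooled dispersion."""
    recs = []
    for day in range(1, 31):
        recs.append(DailyRecord(day=day, times=(4.9, 5.0, 5.1)))
    return recs
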