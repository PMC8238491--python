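import numpy as np
import pytest

from thermocycle.core import Cycle, DailySeries, LhResult, LhSeries, Modality


def make_lh(L, positive_day=None, tested=None):
    """LH series with tests on ``tested`` days (default: all), positive on one."""
    if tested is None:
        tested = range(1, L + 1)
    results = [LhResult.NOT_PERFORMED] * L
    for d in tested:
        results[d - 1] = LhResult.NEGATIVE
    if positive_day is not None:
        results[positive_day - 1] = LhResult.POSITIVE
        for d in range(positive_day + 1, L + 1):
            results[d - 1] = LhResult.NOT_PERFORMED
    return LhSeries(tuple(results))


def make_cycle(wrist, bbt=None, positive_day=None, pid="P001", ci=1, tested=None):
    wrist = np.asarray(wrist, float)
    bbt = wrist.copy() if bbt is None else np.asarray(bbt, float)
    L = wrist.size
    return Cycle.from_series(
        pid, ci,
        DailySeries(Modality.WRIST, wrist),
        DailySeries(Modality.BBT, bbt),
        make_lh(L, positive_day, tested),
    )


@pytest.fixture
def step_cycle():
    """L=29 cycle ovulating on day 15 with a clean 0.3 C luteal step."""
    vals = np.full(29, 36.0)
    vals[15:] = 36.3  # days 16..29 elevated
    return make_cycle(vals, positive_day=14)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
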