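import numpy as np
import pytest

from semilunar import EmergenceSeries, LightRegime


@pytest.fixture
def ld1212():
    return LightRegime(cycle_length_T=24.0)


@pytest.fixture
def ld66():
    return LightRegime(cycle_length_T=12.0)


@pytest.fixture
def daily_series():
    """Build a daily series from float values (NaN marks missing)."""

    def _make(values, start_index=0, regime=None, label=""):
        return EmergenceSeries(
            bin_width=24.0, start_index=start_index, counts=np.asarray(values, float),
            regime=regime, label=label,
        )

    return _make


@pytest.fixture
def hourly_series():
    def _make(values, start_index=0, regime=None, alignment="solar_day"):
        return EmergenceSeries(
            bin_width=1.0, start_index=start_index, counts=np.asarray(values, float),
            regime=regime, alignment=alignment,
        )

    return _make


@pytest.fixture
def cosine_daily(daily_series):
    """82-day series: offset cosine of a given period, rounded to counts."""

    def _make(period, n=82, amp=5.0, offset=10.0, start_index=0):
        t = np.arange(n)
        return daily_series(
            np.round(offset + amp * np.cos(2 * np.pi * t / period)),
            start_index=start_index,
        )

    return _make
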