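"""Series containers, file round-trips and preprocessing rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semilunar import (
    EmergenceEvent,
    EmergenceSeries,
    LightRegime,
    assign_to_solar_days,
    hourly_profile,
    read_series,
    window_semilunar,
    write_series,
    zt_align,
)
from semilunar.exceptions import UnsupportedRegimeError, ValidationError


class TestReadWrite:
    def test_roundtrip_with_missing_tokens(self, tmp_path, daily_series):
        vals = np.arange(141, dtype=float)
        for i in (3, 70, 140):
            vals[i] = np.nan
        s = daily_series(vals, start_index=0, label="rep1")
        path = tmp_path / "daily.csv"
        write_series(path, s)
        assert path.read_text().count("NA") == 3
        back = read_series(path, layout="daily")
        assert len(back) == 1
        assert back[0].n_bins == 141
        assert back[0].missing.sum() == 3
        np.testing.assert_array_equal(back[0].values(), s.values())
        # a second round-trip is bit-exact
        path2 = tmp_path / "again.csv"
        write_series(path2, back[0].replace(label="rep1"))
        assert path.read_text() == path2.read_text()

    def test_hourly_layout_and_multicolumn(self, tmp_path):
        rng = np.random.default_rng(0)
        a = EmergenceSeries(1.0, 1, rng.poisson(2, 2184).astype(float), label="y2022")
        b = EmergenceSeries(1.0, 1, rng.poisson(3, 2184).astype(float), label="y2023")
        path = tmp_path / "hourly.tsv"
        write_series(path, [a, b], sep="\t")
        back = read_series(path, layout="hourly")
        assert [s.label for s in back] == ["y2022", "y2023"]
        assert all(s.n_bins == 2184 and s.bin_width == 1.0 for s in back)
        np.testing.assert_array_equal(back[0].values(), a.values())

    def test_negative_count_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("day,x\n0,4\n1,-1\n")
        with pytest.raises(ValidationError):
            read_series(tmp_path / "bad.csv", layout="daily")

    def test_non_monotone_index_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("day,x\n0,1\n2,1\n1,1\n")
        with pytest.raises(ValidationError):
            read_series(tmp_path / "bad.csv", layout="daily")

    def test_empty_cell_and_nan_token_read_as_missing(self, tmp_path):
        (tmp_path / "na.csv").write_text("day,x\n0,1\n1,\n2,NaN\n3,NA\n")
        (s,) = read_series(tmp_path / "na.csv", layout="daily")
        np.testing.assert_array_equal(s.missing, [False, True, True, True])


class TestSolarDayAssignment:
    def test_t24_identity_no_missing(self, ld1212):
        events = [EmergenceEvent(time=24.0 * d + 12.5) for d in range(10)]
        s = assign_to_solar_days(events, ld1212, n_days=10)
        assert not s.missing.any()
        np.testing.assert_array_equal(s.counts, np.ones(10, int))

    @pytest.mark.parametrize(
        "T, masked_head",
        [(26.0, [6, 19, 32]), (30.0, [2, 7, 12])],
        ids=["T26", "T30"],
    )
    def test_long_cycles_mask_transition_free_days(self, T, masked_head):
        regime = LightRegime(cycle_length_T=T)
        s = assign_to_solar_days([EmergenceEvent(time=T / 2)], regime, n_days=40)
        masked = np.flatnonzero(s.missing)
        assert list(masked[: len(masked_head)]) == masked_head

    def test_masked_day_set_matches_transition_arithmetic(self):
        # masked days = solar days with no dark onset, from first principles
        regime = LightRegime(cycle_length_T=28.0, phase_origin=5.0)
        n_days = 60
        s = assign_to_solar_days([EmergenceEvent(time=20.0)], regime, n_days=n_days)
        onset_days = {
            int((regime.phase_origin + regime.light_duration + m * 28.0) // 24)
            for m in range(200)
        }
        expected = np.array([d not in onset_days for d in range(n_days)])
        np.testing.assert_array_equal(s.missing, expected)

    @settings(max_examples=30, deadline=None)
    @given(
        times=st.lists(st.floats(min_value=13.5, max_value=900.0), min_size=1, max_size=40),
        T=st.sampled_from([22.0, 24.0, 26.0, 30.0]),
    )
    def test_total_count_conserved(self, times, T):
        regime = LightRegime(cycle_length_T=T)
        events = [EmergenceEvent(time=t) for t in times]
        s = assign_to_solar_days(events, regime, n_days=50)
        assert s.total_count == len(times)

    def test_non_ld_regime_rejected(self):
        with pytest.raises(UnsupportedRegimeError):
            assign_to_solar_days(
                [EmergenceEvent(time=1.0)],
                LightRegime(cycle_length_T=24.0, mode="LL"),
                n_days=5,
            )


class TestSemilunarWindow:
    def test_full_series_gives_82_bins_starting_day_31(self, daily_series):
        s = daily_series(np.arange(141.0))
        w = window_semilunar(s)
        assert w.n_bins == 82
        assert w.start_index == 31
        assert w.counts[0] == 31 and w.counts[-1] == 112

    def test_short_series_right_padded_with_missing(self, daily_series):
        s = daily_series(np.ones(100))  # days 0-99
        w = window_semilunar(s)
        assert w.n_bins == 82
        assert w.missing[-13:].all() and not w.missing[:-13].any()

    def test_late_start_rejected(self, daily_series):
        with pytest.raises(ValidationError):
            window_semilunar(daily_series(np.ones(82), start_index=40))


class TestZTAlignment:
    def test_mid_dark_maps_to_zt0(self, hourly_series, ld1212):
        vals = np.zeros(48)
        vals[18] = 7.0  # emergence at clock hour 18 = mid-dark under LD 12:12
        s = hourly_series(vals, regime=ld1212)
        z = zt_align(s)
        assert z.counts[0] == 7 and z.total_count == 7
        assert z.alignment == "zeitgeber_time"

    def test_counts_conserved_and_identity_when_aligned(self, hourly_series, ld1212):
        rng = np.random.default_rng(5)
        s = hourly_series(rng.poisson(3, 96), regime=ld1212)
        z = zt_align(s)
        assert z.total_count == s.total_count
        np.testing.assert_array_equal(zt_align(z).counts, z.counts)

    def test_daily_series_rejected(self, daily_series, ld1212):
        with pytest.raises(UnsupportedRegimeError):
            zt_align(daily_series(np.ones(82)), ld1212)


class TestHourlyProfile:
    def test_single_phase_emergence_concentrates(self, hourly_series):
        vals = np.zeros(240)
        vals[18::24] = 4.0
        prof = hourly_profile(hourly_series(vals), 24)
        assert prof[18] == 40 and prof.sum() == 40

    def test_uniform_counts_give_flat_profile(self, hourly_series):
        prof = hourly_profile(hourly_series(np.full(240, 2.0)), 24)
        np.testing.assert_array_equal(prof, np.full(24, 20.0))

    def test_fold12_vs_fold24_of_one_nightly_peak(self, hourly_series):
        # one peak per 24 h: unimodal at fold 24, collapsed bimodal info at fold 12
        vals = np.zeros(480)
        vals[18::24] = 5.0
        s = hourly_series(vals)
        p24 = hourly_profile(s, 24)
        p12 = hourly_profile(s, 12)
        assert np.count_nonzero(p24) == 1
        assert p12[6] == p24.sum()  # 18 mod 12 -> everything lands on one bin
        # folding cannot tell hour 6 from hour 18 anymore
        assert p12.sum() == p24.sum()

    def test_missing_bins_skipped_total_conserved(self, hourly_series):
        vals = np.full(48, 3.0)
        vals[5] = np.nan
        prof = hourly_profile(hourly_series(vals), 24)
        assert prof.sum() == 47 * 3

    def test_bad_fold_period(self, hourly_series):
        with pytest.raises(ValidationError):
            hourly_profile(hourly_series(np.ones(48)), 0)
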