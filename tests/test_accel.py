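"""Accelerometer processing: non-wear rules, day summaries, inclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actiprofiles.accel import (ActivityScores, ChildComposition, CutPoints,
                                DaySummary, EpochSeries, Excluded,
                                build_composition, detect_nonwear,
                                meets_guidelines, score_activities,
                                summarise_day)

EP_MIN = 6   # 10-s epochs per minute


def series_from_counts(counts, start="2022-05-03 08:00:00"):
    ts = pd.date_range(start, periods=len(counts), freq="10s")
    return EpochSeries(child_id="c", timestamps=ts, counts=np.asarray(counts))


def brute_force_nonwear(counts, epoch_s=10, window_min=60,
                        interruption_max_min=2,
                        mode="per_interruption"):
    """Independent oracle: enumerate every pair of zero runs and flag any
    admissible zero-bounded segment of sufficient span (union over pairs).

    Each candidate is verified directly by rescanning its interior nonzero
    runs, independently of the greedy/two-pointer algorithms under test.
    (Segments starting or ending mid-run extend to full runs without
    changing admissibility, so run-boundary pairs realise the same union.)
    """
    counts = np.asarray(counts)
    n = len(counts)
    window_ep = window_min * 60 // epoch_s
    gap_ep = int(interruption_max_min * 60 // epoch_s)
    flagged = np.zeros(n, dtype=bool)
    z = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    starts = np.flatnonzero(np.diff(z) == 1)
    stops = np.flatnonzero(np.diff(z) == -1)
    for a in range(len(starts)):
        for b in range(a, len(starts)):
            s, e = starts[a], stops[b] - 1
            if e - s + 1 < window_ep:
                continue
            runs = []
            i = s
            while i <= e:
                if counts[i] != 0:
                    j = i
                    while j <= e and counts[j] != 0:
                        j += 1
                    runs.append(j - i)
                    i = j
                else:
                    i += 1
            if mode == "per_interruption":
                ok = all(r <= gap_ep for r in runs)
            else:
                ok = sum(runs) <= gap_ep
            if ok:
                flagged[s:e + 1] = True
    return np.flatnonzero(flagged)


class TestDetectNonwear:
    def test_long_zero_run_flagged(self):
        counts = np.r_[np.full(60, 500), np.zeros(70 * EP_MIN, dtype=int),
                       np.full(60, 500)]
        s = series_from_counts(counts)
        idx = detect_nonwear(s)
        assert set(idx) == set(range(60, 60 + 70 * EP_MIN))

    def test_run_below_threshold_not_flagged(self):
        counts = np.r_[np.full(60, 500), np.zeros(59 * EP_MIN, dtype=int),
                       np.full(60, 500)]
        assert detect_nonwear(series_from_counts(counts)).size == 0

    def test_interrupted_run_merged(self):
        # 40 min zeros + 1 min nonzero + 40 min zeros: all 81 min flagged
        counts = np.r_[np.full(6, 900), np.zeros(40 * EP_MIN, dtype=int),
                       np.full(1 * EP_MIN, 200),
                       np.zeros(40 * EP_MIN, dtype=int), np.full(6, 900)]
        idx = detect_nonwear(series_from_counts(counts))
        assert set(idx) == set(range(6, 6 + 81 * EP_MIN))

    def test_long_interruption_splits_run(self):
        counts = np.r_[np.zeros(40 * EP_MIN, dtype=int),
                       np.full(3 * EP_MIN, 200),
                       np.zeros(40 * EP_MIN, dtype=int)]
        assert detect_nonwear(series_from_counts(counts)).size == 0

    def test_midnight_to_six_always_flagged(self):
        counts = np.full(7 * 60 * EP_MIN, 500)   # active 00:00-07:00
        s = series_from_counts(counts, start="2022-05-03 00:00:00")
        idx = set(detect_nonwear(s))
        assert idx == set(range(6 * 60 * EP_MIN))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            EpochSeries(child_id="c", timestamps=pd.DatetimeIndex([]),
                        counts=np.array([]))

    @pytest.mark.parametrize("mode", ["per_interruption", "total_budget"])
    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, mode, data):
        """Run-merging agrees with exhaustive segment enumeration on random
        short streams with frequent zeros."""
        n = data.draw(st.integers(80, 260))
        counts = np.array(data.draw(st.lists(
            st.sampled_from([0, 0, 0, 40, 700]), min_size=n, max_size=n)))
        s = series_from_counts(counts)
        got = detect_nonwear(s, window_min=3, interruption_max_min=0.5,
                             interruption_mode=mode)
        want = brute_force_nonwear(counts, window_min=3,
                                   interruption_max_min=0.5, mode=mode)
        assert np.array_equal(got, want)


class TestSummariseDay:
    def test_all_zero_day_invalid(self):
        counts = np.zeros(18 * 60 * EP_MIN, dtype=int)
        s = series_from_counts(counts, start="2022-05-03 06:00:00")
        d = summarise_day(s, "2022-05-03")
        assert d.wear_minutes == 0 and not d.valid

    def test_single_class_day(self):
        cp = CutPoints()
        counts = np.full(600 * EP_MIN, (cp.sed_max + cp.mvpa_min) // 2)
        s = series_from_counts(counts, start="2022-05-03 06:00:00")
        d = summarise_day(s, "2022-05-03", cutpoints=cp)
        assert d.lpa_minutes == 600 and d.valid

    def test_constructed_day_counts(self):
        cp = CutPoints()
        counts = np.r_[
            np.full(30 * EP_MIN, cp.mvpa_min + 10),     # 30 min MVPA
            np.full(300 * EP_MIN, cp.sed_max),          # 300 min sedentary
            np.full(200 * EP_MIN, cp.sed_max + 5),      # 200 min light
            np.zeros(90 * EP_MIN, dtype=int),           # >=60 min: non-wear
        ]
        s = series_from_counts(counts, start="2022-05-03 06:00:00")
        d = summarise_day(s, "2022-05-03", cutpoints=cp)
        assert (d.mvpa_minutes, d.sed_minutes, d.lpa_minutes) == (30, 300, 200)
        assert d.valid

    def test_minutes_conserved(self, rng):
        counts = rng.integers(0, 1200, 18 * 60 * EP_MIN)
        s = series_from_counts(counts, start="2022-05-03 06:00:00")
        d = summarise_day(s, "2022-05-03")
        assert d.sed_minutes + d.lpa_minutes + d.mvpa_minutes == pytest.approx(
            d.wear_minutes, abs=1e-9)

    def test_absent_date_errors(self):
        s = series_from_counts(np.full(60, 100))
        with pytest.raises(ValueError):
            summarise_day(s, "1999-01-01")

    def test_valid_day_threshold_monotone(self, rng):
        """Raising the valid-day threshold never turns an invalid day valid."""
        counts = rng.integers(0, 400, 18 * 60 * EP_MIN)
        s = series_from_counts(counts, start="2022-05-03 06:00:00")
        valid = [summarise_day(s, "2022-05-03", valid_day_min=v).valid
                 for v in (200, 400, 600, 800)]
        assert valid == sorted(valid, reverse=True)


def _day(child="c", date="2022-05-02", wear=600.0, mvpa=60.0, sed=300.0,
         valid=True):
    date = pd.Timestamp(date)
    return DaySummary(child_id=child, date=date.date(),
                      day_type="weekend" if date.dayofweek >= 5 else
                      "weekday", wear_minutes=wear, sed_minutes=sed,
                      lpa_minutes=wear - sed - mvpa, mvpa_minutes=mvpa,
                      valid=valid)


class TestBuildComposition:
    def test_full_week_included(self):
        days = [_day(date=f"2022-05-0{d}") for d in range(2, 7)] + \
               [_day(date="2022-05-07"), _day(date="2022-05-08")]
        comp = build_composition(days)
        assert isinstance(comp, ChildComposition)
        assert not comp.weekend_missing
        assert comp.n_valid_weekdays == 5 and comp.n_valid_weekend == 2

    def test_single_weekday_excluded(self):
        res = build_composition([_day(date="2022-05-02")])
        assert isinstance(res, Excluded)

    def test_no_weekend_excluded_by_default_kept_in_sensitivity_mode(self):
        days = [_day(date=f"2022-05-0{d}") for d in (2, 3, 4)]
        assert isinstance(build_composition(days), Excluded)
        comp = build_composition(days, allow_missing_weekend=True)
        assert isinstance(comp, ChildComposition) and comp.weekend_missing

    def test_proportion_arithmetic(self):
        days = [_day(date=f"2022-05-0{d}", wear=600, mvpa=60, sed=300)
                for d in (2, 3, 4)] + [_day(date="2022-05-07")]
        comp = build_composition(days)
        assert comp.p_mvpa_wd == pytest.approx(0.10)
        assert comp.p_sed_wd == pytest.approx(0.50)

    def test_invalid_days_not_counted(self):
        days = ([_day(date="2022-05-02"), _day(date="2022-05-03",
                                               valid=False)]
                + [_day(date="2022-05-07")])
        assert isinstance(build_composition(days), Excluded)


class TestGuidelines:
    def _comp(self, wd_min, we_min, wear=700.0):
        return ChildComposition(child_id="c", p_mvpa_wd=wd_min / wear,
                                p_sed_wd=0.5, p_mvpa_we=we_min / wear,
                                p_sed_we=0.5, wear_wd=wear, wear_we=wear)

    @pytest.mark.parametrize("wd,we,expected", [
        (70, 70, True),
        (60, 60, True),       # boundary is inclusive
        (65, 40, False),      # (325 + 80)/7 = 57.9
        (59.9, 59.9, False),
    ])
    def test_weighted_average_rule(self, wd, we, expected):
        assert meets_guidelines(self._comp(wd, we)) is expected

    def test_missing_weekend_gives_missing(self):
        c = self._comp(70, 70)
        c.p_mvpa_we = np.nan
        assert meets_guidelines(c) is None


class TestScoreActivities:
    @pytest.mark.parametrize("a,b,expected", [
        (0, 0, 0.0),
        (3, 3, 6.0),
        (1, 2, 2.5),       # midpoints 1.5 and 3.5
    ])
    def test_structured_midpoints(self, a, b, expected):
        s = score_activities("c", a, b, 0, 0)
        assert s.structured_days == pytest.approx(expected)

    def test_single_missing_item_uses_other(self):
        s = score_activities("c", None, 2, 1, None)
        assert s.structured_days == pytest.approx(3.5)
        assert s.unstructured_days == pytest.approx(1.5)

    def test_pair_fully_missing_gives_missing(self):
        s = score_activities("c", None, None, 1, 1)
        assert np.isnan(s.structured_days)
        assert s.unstructured_days == pytest.approx(1.5)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            score_activities("c", 5, 0, 0, 0)
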