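import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scanopt import (
    SamplingScheme,
    ScanTable,
    ValidationError,
    occurrence_continuous,
    occurrence_from_scans,
    scan_sample,
    scan_times,
    simulate_flock,
    table3_preset,
)

from conftest import build_timeline


class TestScanTimes:
    @pytest.mark.parametrize(
        "duration,interval,expected_n",
        [(7200.0, 600.0, 12), (7200.0, 300.0, 24), (7200.0, 900.0, 8), (7200.0, 1800.0, 4)],
    )
    def test_scans_per_two_hour_session(self, duration, interval, expected_n):
        times = scan_times(duration, interval)
        assert len(times) == expected_n
        assert times[0] == interval
        assert times[-1] == pytest.approx(duration)

    def test_boundary_single_scan(self):
        assert list(scan_times(7200.0, 7200.0)) == [7200.0]

    def test_interval_longer_than_session_is_empty(self):
        assert len(scan_times(600.0, 900.0)) == 0

    def test_offset_anchor(self):
        assert list(scan_times(3600.0, 900.0, offset_s=450.0)) == [450.0, 1350.0, 2250.0, 3150.0]

    def test_long_interval_scans_nest_in_short_when_divisible(self):
        t30 = set(scan_times(7200.0, 1800.0))
        assert t30 <= set(scan_times(7200.0, 900.0))
        assert t30 <= set(scan_times(7200.0, 600.0))


class TestScanSample:
    def test_constant_walker_counted_every_scan(self):
        tl = build_timeline({"a1": [(0.0, 7200.0, "Walking")]}, 7200.0)
        table = scan_sample(tl, SamplingScheme(600.0))
        assert (table.scans["visible_count"] == 1).all()
        assert (table.scans["Walking"] == 1).all()

    def test_invisible_at_one_scan_decrements_visible_count(self):
        tl = build_timeline(
            {"a1": [(0.0, 7200.0, "Walking")]},
            7200.0,
            visibility={"a1": [(0.0, 1150.0, True), (1150.0, 1250.0, False),
                               (1250.0, 7200.0, True)]},
        )
        table = scan_sample(tl, SamplingScheme(600.0))
        by_time = table.scans.set_index("time_s")
        assert by_time.loc[1200.0, "visible_count"] == 0
        assert by_time.loc[600.0, "visible_count"] == 1
        assert int(table.scans["visible_count"].sum()) == 11

    def test_window_majority_picks_dominant_behavior(self):
        # in the 10-s window before the scan: 6 s walking, then 4 s resting
        tl = build_timeline(
            {"a1": [(0.0, 596.0, "Walking"), (596.0, 7200.0, "Resting")]}, 7200.0
        )
        table = scan_sample(
            tl, SamplingScheme(600.0, window_s=10.0, mode="window_majority")
        )
        first = table.scans.set_index("time_s").loc[600.0]
        assert first["Walking"] == 1 and first["Resting"] == 0

    def test_window_majority_tie_goes_to_behavior_at_scan_time(self):
        tl = build_timeline(
            {"a1": [(0.0, 595.0, "Walking"), (595.0, 7200.0, "Resting")]}, 7200.0
        )
        table = scan_sample(
            tl, SamplingScheme(600.0, window_s=10.0, mode="window_majority")
        )
        first = table.scans.set_index("time_s").loc[600.0]
        assert first["Resting"] == 1

    def test_window_majority_visibility_threshold(self):
        # visible for only 4 of the 10 s window -> not counted at that scan
        tl = build_timeline(
            {"a1": [(0.0, 7200.0, "Walking")]},
            7200.0,
            visibility={"a1": [(0.0, 594.0, True), (594.0, 600.0, False),
                               (600.0, 7200.0, True)]},
        )
        table = scan_sample(
            tl, SamplingScheme(600.0, window_s=10.0, mode="window_majority")
        )
        assert table.scans.set_index("time_s").loc[600.0, "visible_count"] == 0

    def test_counts_sum_to_visible(self, ethogram):
        tl = simulate_flock(table3_preset(n_animals=10, duration_s=3600.0, seed=2))
        table = scan_sample(tl, SamplingScheme(300.0), ethogram)
        total = table.scans[table.behavior_columns].sum(axis=1)
        assert (total == table.scans["visible_count"]).all()


class TestOccurrenceFromScans:
    def _table(self, rows, behaviors=("Walking", "Resting")):
        scans = pd.DataFrame(rows, columns=["time_s", "visible_count", *behaviors])
        return ScanTable("s1", 600.0, 0.0, scans)

    def test_mean_of_per_scan_proportions(self):
        t = self._table([(600.0, 10, 1, 9), (1200.0, 10, 2, 8)])
        occ = occurrence_from_scans(t).set_index("behavior")["value"]
        assert occ["Walking"] == pytest.approx(15.0)
        assert occ["Resting"] == pytest.approx(85.0)

    def test_never_observed_behavior_is_zero(self):
        t = self._table([(600.0, 10, 10, 0)])
        assert occurrence_from_scans(t).set_index("behavior")["value"]["Resting"] == 0.0

    def test_zero_visible_scan_excluded_from_mean(self):
        t = self._table([(600.0, 50, 10, 40), (1200.0, 50, 20, 30), (1800.0, 0, 0, 0)])
        occ = occurrence_from_scans(t).set_index("behavior")["value"]
        # mean over the two usable scans only: (20 + 40) / 2
        assert occ["Walking"] == pytest.approx(30.0)

    def test_all_scans_zero_visible_is_error(self):
        t = self._table([(600.0, 0, 0, 0), (1200.0, 0, 0, 0)])
        with pytest.raises(ValidationError, match="visible"):
            occurrence_from_scans(t)

    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)),
            min_size=1,
            max_size=8,
        ).filter(lambda rows: any(sum(r) > 0 for r in rows))
    )
    def test_occurrences_sum_to_100(self, count_rows):
        rows = [
            (600.0 * (i + 1), sum(r), *r) for i, r in enumerate(count_rows)
        ]
        t = self._table(rows, behaviors=("Walking", "Resting", "Hiding"))
        occ = occurrence_from_scans(t)
        assert occ["value"].sum() == pytest.approx(100.0, abs=1e-9)


class TestOccurrenceContinuous:
    def test_half_and_half(self, walker_rester):
        occ = occurrence_continuous(walker_rester).set_index("behavior")["value"]
        assert occ["Walking"] == pytest.approx(50.0)
        assert occ["Resting"] == pytest.approx(50.0)

    def test_visibility_weighting(self):
        # invisible during all resting time: only walking is observable
        tl = build_timeline(
            {"a1": [(0.0, 60.0, "Walking"), (60.0, 120.0, "Resting")]},
            120.0,
            visibility={"a1": [(0.0, 60.0, True), (60.0, 120.0, False)]},
        )
        occ = occurrence_continuous(tl).set_index("behavior")["value"]
        assert occ["Walking"] == pytest.approx(100.0)

    def test_never_visible_is_error(self):
        tl = build_timeline(
            {"a1": [(0.0, 120.0, "Walking")]},
            120.0,
            visibility={"a1": [(0.0, 120.0, False)]},
        )
        with pytest.raises(ValidationError, match="visible"):
            occurrence_continuous(tl)

    def test_values_sum_to_100(self, ethogram):
        tl = simulate_flock(table3_preset(n_animals=8, duration_s=3600.0, seed=4))
        occ = occurrence_continuous(tl, ethogram)
        assert occ["value"].sum() == pytest.approx(100.0, abs=1e-9)


def test_short_interval_scans_converge_to_continuous(ethogram):
    # at 1-min scans the subsampling error is far below the bout scale
    tl = simulate_flock(table3_preset(n_animals=20, duration_s=7200.0, seed=6))
    cont = occurrence_continuous(tl, ethogram).set_index("behavior")["value"]
    occ = occurrence_from_scans(
        scan_sample(tl, SamplingScheme(60.0), ethogram)
    ).set_index("behavior")["value"]
    assert float((occ - cont).abs().mean()) < 0.5
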