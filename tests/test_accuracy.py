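import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scanopt import (
    ValidationError,
    bin_behaviors,
    bland_altman,
    compare_error_distributions,
    error_scores,
    limits_of_agreement,
    reference_metrics,
    select_reference,
    summarize_errors,
)
from scanopt.accuracy import LOA_MULTIPLIER


def occ_df(values, method="10min", sessions=None, behaviors=None):
    n = len(values)
    sessions = sessions or [f"s{i}" for i in range(n)]
    behaviors = behaviors or ["Walking"] * n
    return pd.DataFrame(
        {"session_id": sessions, "method": method, "behavior": behaviors, "value": values}
    )


class TestReferenceMetrics:
    def test_perfect_candidate(self):
        truth = occ_df([1.0, 2.0, 3.0], method="continuous")
        cand = occ_df([1.0, 2.0, 3.0])
        m = reference_metrics(cand, truth)
        assert m["r2"] == pytest.approx(1.0)
        assert m["mae"] == 0.0
        assert m["rmse"] == 0.0

    def test_hand_computed_errors(self):
        truth = occ_df([1.0, 2.0, 3.0], method="continuous")
        cand = occ_df([1.0, 3.0, 5.0])
        m = reference_metrics(cand, truth)
        assert m["mae"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(math.sqrt(5.0 / 3.0))

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            truth = occ_df(rng.uniform(0, 30, size=8), method="continuous")
            cand = occ_df(rng.uniform(0, 30, size=8))
            m = reference_metrics(cand, truth)
            assert m["rmse"] >= m["mae"]

    def test_too_few_pairs_rejected(self):
        truth = occ_df([1.0, 2.0], method="continuous")
        with pytest.raises(ValidationError):
            reference_metrics(occ_df([1.0, 2.0]), truth)


class TestSelectReference:
    def test_observed_metrics_shape_selects_10min(self):
        metrics = {
            "10min": {"r2": 0.521, "mae": 3.73, "rmse": 7.68},
            "15min": {"r2": 0.435, "mae": 3.93, "rmse": 8.33},
            "30min": {"r2": 0.386, "mae": 4.58, "rmse": 8.69},
        }
        assert select_reference(metrics).chosen == "10min"

    def test_single_candidate(self):
        assert select_reference({"15min": {"r2": 0.3, "mae": 1, "rmse": 2}}).chosen == "15min"

    def test_majority_beats_single_criterion(self):
        # one candidate wins R2 only, the other wins both error criteria
        metrics = {
            "10min": {"r2": 0.9, "mae": 4.0, "rmse": 9.0},
            "30min": {"r2": 0.5, "mae": 3.0, "rmse": 7.0},
        }
        assert select_reference(metrics).chosen == "30min"

    def test_tie_goes_to_shortest_interval(self):
        same = {"r2": 0.5, "mae": 3.0, "rmse": 7.0}
        assert select_reference({"30min": dict(same), "10min": dict(same)}).chosen == "10min"


class TestBinBehaviors:
    def test_boundaries_match_stated_thresholds(self):
        ref = occ_df(
            [0.49, 0.50, 3.50, 3.51],
            behaviors=["A", "B", "C", "D"],
            sessions=["s1"] * 4,
        )
        cats = bin_behaviors(ref)
        assert cats == {"A": "low", "B": "medium", "C": "medium", "D": "high"}

    def test_observed_values_fall_in_reported_categories(self):
        ref = occ_df(
            [0.92, 14.39, 0.46], behaviors=["Drinking", "Grass pecking", "Attacking"],
            sessions=["s1"] * 3,
        )
        cats = bin_behaviors(ref)
        assert cats["Drinking"] == "medium"
        assert cats["Grass pecking"] == "high"
        assert cats["Attacking"] == "low"

    def test_excluded_behavior_skipped(self, ethogram):
        ref = occ_df([1.0, 1.0], behaviors=["Others", "Walking"], sessions=["s1"] * 2)
        cats = bin_behaviors(ref, ethogram=ethogram)
        assert "Others" not in cats and "Walking" in cats

    def test_means_over_sessions_are_binned(self):
        ref = occ_df([0.2, 0.8], behaviors=["A", "A"], sessions=["s1", "s2"])
        assert bin_behaviors(ref) == {"A": "medium"}  # mean 0.5 > 0.49


class TestErrorScores:
    def test_identical_records_give_zero(self):
        ref = occ_df([1.0, 2.0, 3.0])
        assert (error_scores(ref, ref)["error"] == 0).all()

    def test_underestimation_is_negative(self):
        ref = occ_df([0.46], method="10min", sessions=["s1"])
        test = occ_df([0.24], method="30min", sessions=["s1"])
        assert error_scores(test, ref)["error"].iloc[0] == pytest.approx(-0.22)

    def test_antisymmetric(self):
        a = occ_df([1.0, 5.0, 2.0])
        b = occ_df([2.0, 3.0, 9.0], method="30min")
        fwd = error_scores(a, b)["error"].to_numpy()
        rev = error_scores(b, a)["error"].to_numpy()
        assert np.allclose(fwd, -rev)

    def test_unmatched_record_named_in_error(self):
        a = occ_df([1.0, 2.0], sessions=["s1", "s2"])
        b = occ_df([1.0], method="30min", sessions=["s1"])
        with pytest.raises(ValidationError, match="s2"):
            error_scores(a, b)


class TestSummarizeErrors:
    def _errors(self, values, behavior="Attacking"):
        return pd.DataFrame(
            {"session_id": [f"s{i}" for i in range(len(values))],
             "behavior": behavior, "error": values}
        )

    def test_symmetric_errors_not_significant(self):
        s = summarize_errors(self._errors([-1.0, 1.0, -2.0, 2.0]), {"Attacking": "low"})
        row = s.iloc[0]
        assert row["mean_error"] == 0.0
        assert row["ci_low"] < 0 < row["ci_high"]
        assert not row["significant"]

    def test_consistent_underestimation_flagged(self):
        s = summarize_errors(self._errors([-0.2, -0.3, -0.25, -0.15]), {"Attacking": "low"})
        assert s.iloc[0]["significant"]
        assert s.iloc[0]["ci_high"] < 0

    def test_t_interval_matches_hand_computation(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]  # mean 3, sd sqrt(2.5), n 5
        s = summarize_errors(self._errors(vals), {"Attacking": "low"})
        t975_df4 = 2.7764451051977987
        half = t975_df4 * math.sqrt(2.5) / math.sqrt(5)
        assert s.iloc[0]["ci_low"] == pytest.approx(3 - half)
        assert s.iloc[0]["ci_high"] == pytest.approx(3 + half)

    def test_uncategorized_behaviors_dropped(self):
        s = summarize_errors(self._errors([1.0, 2.0], behavior="Mystery"), {})
        assert s.empty


class TestWilcoxon:
    def test_identical_sets_give_p_one(self):
        res = compare_error_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_exact_p_matches_sign_flip_enumeration(self):
        a = np.array([1.3, -0.7, 2.1, 0.4, -1.9, 0.9])
        b = np.zeros(6)
        res = compare_error_distributions(a, b)
        assert res.method == "exact"
        # enumerate all 2^6 sign assignments of the |difference| ranks
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(a))
        w_obs = ranks[a > 0].sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=6)
        ]
        n_le = sum(w <= w_obs for w in dist)
        n_ge = sum(w >= w_obs for w in dist)
        p_exact = min(1.0, 2 * min(n_le, n_ge) / len(dist))
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        res = compare_error_distributions(base + 10.0, base)
        assert res.p_value < 0.05


class TestBlandAltman:
    def test_reported_loa_arithmetic(self):
        lo, hi = limits_of_agreement(-0.0003, 2.558)
        assert lo == pytest.approx(-5.014, abs=1e-3)
        assert hi == pytest.approx(5.013, abs=1e-3)

    def test_identical_methods(self):
        a = occ_df([1.0, 2.0, 3.0])
        b = occ_df([1.0, 2.0, 3.0], method="30min")
        res = bland_altman(a, b)
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_percent_mode_hand_arithmetic(self):
        a = occ_df([2.0, 4.0, 2.0, 4.0])
        b = occ_df([1.0, 5.0, 1.0, 5.0], method="30min")
        res = bland_altman(a, b, mode="percent")
        assert sorted(set(np.round(res.points["diff"], 6))) == [-25.0, 50.0]
        assert res.bias == pytest.approx(12.5)

    def test_percent_mode_drops_zero_reference_pairs(self):
        a = occ_df([0.0, 2.0, 4.0, 3.0])
        b = occ_df([1.0, 1.0, 5.0, 3.0], method="30min")
        res = bland_altman(a, b, mode="percent")
        assert res.n_dropped == 1
        assert res.n == 3

    def test_raw_mode_uses_pair_mean_axis(self):
        a = occ_df([2.0, 4.0, 6.0])
        b = occ_df([4.0, 2.0, 6.0], method="30min")
        res = bland_altman(a, b)
        assert list(res.points["mean"]) == [3.0, 3.0, 6.0]
        assert list(res.points["diff"]) == [-2.0, 2.0, 0.0]

    def test_too_few_pairs_rejected(self):
        a = occ_df([1.0, 2.0])
        b = occ_df([2.0, 1.0], method="30min")
        with pytest.raises(ValidationError):
            bland_altman(a, b)

    def test_raw_bias_near_zero_between_unbiased_subsamplings(self):
        # two scan grids over the same timelines both estimate the same
        # truth, so their raw differences center on zero
        from scanopt import (
            SamplingScheme,
            occurrence_from_scans,
            scan_sample,
            simulate_flock,
            table3_preset,
        )

        frames = {600.0: [], 900.0: []}
        for s in range(6):
            cfg = table3_preset(n_animals=25, seed=300 + s)
            tl = simulate_flock(cfg, session_id=f"s{s}")
            for iv in frames:
                frames[iv].append(
                    occurrence_from_scans(
                        scan_sample(tl, SamplingScheme(interval_s=iv), cfg.ethogram)
                    )
                )
        res = bland_altman(
            pd.concat(frames[600.0], ignore_index=True),
            pd.concat(frames[900.0], ignore_index=True),
            mode="raw",
        )
        assert abs(res.bias) < 0.3

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=3,
            max_size=20,
        )
    )
    def test_loa_width_closed_form(self, pairs):
        a = occ_df([p[0] for p in pairs])
        b = occ_df([p[1] for p in pairs], method="30min")
        res = bland_altman(a, b)
        assert res.loa_high - res.loa_low == pytest.approx(
            2 * LOA_MULTIPLIER * res.sd_diff, rel=1e-9, abs=1e-9
        )
        assert res.loa_low <= res.bias <= res.loa_high
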