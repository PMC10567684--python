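import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scanopt import (
    ValidationError,
    compare_effect_sizes,
    fit_tweedie_glm,
    friedman_test,
    pairwise_posthoc,
)
from scanopt.inference import _friedman_stat


def brute_force_friedman_p(x):
    """Full enumeration over all within-block orderings of the observed values."""
    ranks = np.apply_along_axis(stats.rankdata, 1, np.asarray(x, dtype=float))
    s_obs, _, _ = _friedman_stat(ranks)
    hits = total = 0
    for perms in itertools.product(*[list(itertools.permutations(row)) for row in ranks]):
        s, _, _ = _friedman_stat(np.array(perms))
        total += 1
        hits += s >= s_obs - 1e-9
    return hits / total


class TestFriedman:
    def test_identical_columns(self):
        x = np.tile(np.array([[1.0], [5.0], [3.0]]), (1, 3))
        res = friedman_test(x)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "table",
        [
            [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0]],
            [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]],
            [[1.0, 1.0, 2.0], [3.0, 2.0, 2.0], [1.0, 2.0, 3.0]],  # with ties
        ],
    )
    def test_exact_p_matches_enumeration(self, table):
        res = friedman_test(np.array(table), method="exact")
        assert res.p_value == pytest.approx(brute_force_friedman_p(table), abs=1e-12)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(14, 3))
        res = friedman_test(x, method="asymptotic")
        ref = stats.friedmanchisquare(*x.T)
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 1))
        x = np.hstack([base, base + rng.normal(0, 0.1, size=(10, 1)), base + 2.0])
        assert friedman_test(x).p_value < 0.05

    def test_incomplete_block_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValidationError, match="incomplete"):
            friedman_test(x)


class TestPosthoc:
    def test_no_differences_share_a_letter(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(10, 3)), columns=["10min", "15min", "30min"])
        res = pairwise_posthoc(x)
        assert set(res.letters.values()) == {"a"}

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(8, 3)))
        res = pairwise_posthoc(x)
        for _, row in res.table.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p_raw"]))

    def test_outer_pair_difference_yields_a_ab_b(self):
        # methods 1-2 and 2-3 do not differ; 1-3 differ consistently
        base = np.arange(10, dtype=float)
        step = np.tile([0.6, -0.4], 5)
        m1 = base
        m2 = base + step
        m3 = m2 + np.roll(step, 1) + 0.0
        # d13 = step + roll(step) = +0.2 everywhere -> consistent difference
        x = pd.DataFrame({"m1": m1, "m2": m2, "m3": m3})
        res = pairwise_posthoc(x)
        assert res.letters == {"m1": "a", "m2": "ab", "m3": "b"}


class TestTweedieGLM:
    def _toy(self, seed=0, n=24):
        rng = np.random.default_rng(seed)
        y = rng.gamma(2.0, 1.0, size=n)
        y[rng.random(n) < 0.2] = 0.0
        return pd.DataFrame(
            {"value": y, "group": ["A"] * (n // 2) + ["B"] * (n // 2),
             "day": list(range(1, n // 2 + 1)) * 2}
        )

    def test_intercept_only_recovers_sample_mean(self):
        d = self._toy().drop(columns=["group"])
        for power in (1.2, 1.5, 1.8):
            fit = fit_tweedie_glm(d, group=None, day=None, power=power)
            assert np.exp(fit.term("Intercept")["coef"]) == pytest.approx(
                d["value"].mean(), rel=1e-6
            )

    def test_saturated_two_group_model_recovers_group_means(self):
        d = self._toy(seed=1)
        fit = fit_tweedie_glm(d, day=None)
        means = d.groupby("group")["value"].mean()
        assert fit.fitted_means["A"] == pytest.approx(means["A"], rel=1e-6)
        assert fit.fitted_means["B"] == pytest.approx(means["B"], rel=1e-6)
        assert fit.term("group[B]")["or"] == pytest.approx(means["B"] / means["A"], rel=1e-6)

    def test_wald_se_matches_finite_difference_fisher_information(self):
        d = self._toy(seed=2, n=20)
        power = 1.5
        fit = fit_tweedie_glm(d, power=power)
        # reconstruct the expected information with a numerical Jacobian of
        # the mean function mu(beta) = exp(X beta)
        X = np.column_stack(
            [np.ones(len(d)), (d["group"] == "B").astype(float), d["day"].astype(float)]
        )
        beta = fit.terms["coef"].to_numpy()
        eps = 1e-6

        def mu(b):
            return np.exp(X @ b)

        D = np.column_stack(
            [
                (mu(beta + eps * np.eye(3)[j]) - mu(beta - eps * np.eye(3)[j])) / (2 * eps)
                for j in range(3)
            ]
        )
        V = mu(beta) ** power
        info = D.T @ (D / V[:, None]) / fit.dispersion
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.allclose(fit.terms["se"].to_numpy(), se, rtol=1e-4)

    def test_or_confidence_interval_brackets_or(self):
        fit = fit_tweedie_glm(self._toy(seed=3))
        t = fit.term("group[B]")
        assert t["ci_low"] <= t["or"] <= t["ci_high"]
        assert t["or"] > 0

    def test_all_zero_group_rejected(self):
        d = self._toy(seed=4)
        d.loc[d["group"] == "B", "value"] = 0.0
        with pytest.raises(ValidationError, match="all-zero"):
            fit_tweedie_glm(d)

    def test_power_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            fit_tweedie_glm(self._toy(), power=2.5)


class TestEffectRecovery:
    def test_tweedie_or_recovers_simulated_mean_ratio(self):
        """A 2x occupancy effect on a medium-occurrence behavior is
        recovered on the log scale at 20 sessions/group."""
        from scanopt import (
            GroupEffectConfig,
            GroupSpec,
            SamplingScheme,
            occurrence_from_scans,
            scan_sample,
            simulate_study,
            table3_preset,
        )
        from scanopt.simulate import apply_group_effects

        behavior, factor = "Hiding", 2.0
        base0 = table3_preset()
        occ_b = apply_group_effects(base0.target_occupancy, {behavior: factor})
        true_log_ratio = np.log(occ_b[behavior] / base0.target_occupancy[behavior])
        log_errors = []
        for rep in range(3):
            base = table3_preset(n_animals=50, seed=500 + rep)
            cfg = GroupEffectConfig(
                base=base,
                groups=(GroupSpec("A"), GroupSpec("B", {behavior: factor})),
                sessions_per_group=20,
            )
            rows = []
            for tl in simulate_study(cfg):
                occ = occurrence_from_scans(
                    scan_sample(tl, SamplingScheme(600.0), base.ethogram)
                )
                rows.append(
                    {"value": float(occ.loc[occ["behavior"] == behavior, "value"].iloc[0]),
                     "group": tl.group, "day": tl.day}
                )
            fit = fit_tweedie_glm(pd.DataFrame(rows))
            log_errors.append(float(fit.term("group[B]")["coef"]) - true_log_ratio)
        assert abs(np.mean(log_errors)) < 0.1


class TestCompareEffectSizes:
    def test_identical_estimates(self):
        res = compare_effect_sizes(0.3, 0.1, 0.3, 0.1)
        assert res.z == 0.0
        assert res.p_value == 1.0

    def test_normal_cdf_oracle(self):
        res = compare_effect_sizes(0.5, 0.2, 0.0, 0.15)
        assert res.z == pytest.approx(2.0)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)

    def test_antisymmetric(self):
        a = compare_effect_sizes(0.5, 0.2, 0.1, 0.15)
        b = compare_effect_sizes(0.1, 0.15, 0.5, 0.2)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_ses_rejected(self):
        with pytest.raises(ValidationError):
            compare_effect_sizes(0.5, 0.0, 0.1, 0.0)
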