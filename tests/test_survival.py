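"""Kaplan-Meier, log-rank, Cox, interaction LRT, Spearman/BH, robust z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ringquant.survival import (
    cox_multivariate,
    interaction_lrt,
    kaplan_meier,
    logrank_test,
    robust_zscore,
    spearman_bh,
)


def _records(times, events, groups, **covs):
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    for k, v in covs.items():
        df[k] = v
    return df


def brute_force_logrank(df):
    """Independent oracle: explicit risk tables at every event time."""
    o1 = e1 = v = 0.0
    for t in sorted(df.loc[df.event, "time"].unique()):
        at_risk = df[df.time >= t]
        n = len(at_risk)
        n1 = (at_risk.group == "high").sum()
        dead = df[(df.time == t) & df.event]
        d = len(dead)
        d1 = (dead.group == "high").sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v if v > 0 else 0.0


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = kaplan_meier(_records([5, 10, 15], [False] * 3, ["low"] * 3))
        assert (km["survival"] == 1.0).all()

    def test_all_events_closed_form(self):
        km = kaplan_meier(_records([1, 2, 3], [True] * 3, ["low"] * 3))
        s = km.set_index("time")["survival"]
        assert s.loc[1] == pytest.approx(2 / 3)
        assert s.loc[2] == pytest.approx(1 / 3)
        assert s.loc[3] == pytest.approx(0.0)

    def test_curve_flat_beyond_last_event_with_censoring(self):
        km = kaplan_meier(_records([1, 2, 5, 8], [True, True, False, False], ["low"] * 4))
        s = km.set_index("time")["survival"]
        assert s.loc[5] == s.loc[2]
        assert s.loc[8] == s.loc[2]

    def test_monotone_nonincreasing_starts_at_one(self):
        km = kaplan_meier(
            _records([3, 1, 4, 1, 5, 9], [1, 1, 0, 1, 0, 1], ["low"] * 3 + ["high"] * 3)
        )
        for _, grp in km.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(_records([0, 1], [True, True], ["low", "low"]))


SMALL_FIXTURES = [
    # (times, events, groups) — all <= 12 patients, with and without ties
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], ["high", "low"] * 3),
    ([2, 2, 3, 3, 5, 7], [1, 1, 1, 0, 1, 1], ["high", "high", "low", "low", "high", "low"]),
    ([1, 1, 1, 2, 2, 9, 9, 10], [1, 1, 0, 1, 1, 1, 0, 1],
     ["high", "low", "low", "high", "low", "high", "low", "high"]),
    ([4, 8, 15, 16, 23, 42, 5, 7, 11, 13, 2, 3], [1] * 6 + [0, 1, 1, 0, 1, 1],
     ["high"] * 6 + ["low"] * 6),
]


class TestLogrank:
    @pytest.mark.parametrize("times,events,groups", SMALL_FIXTURES)
    def test_matches_brute_force_risk_table_oracle(self, times, events, groups):
        df = _records(times, list(map(bool, events)), groups)
        result = logrank_test(df)
        assert result.statistic == pytest.approx(brute_force_logrank(df), abs=1e-12)

    @pytest.mark.parametrize("times,events,groups", SMALL_FIXTURES)
    def test_matches_lifelines_statistic(self, times, events, groups):
        from lifelines.statistics import logrank_test as ll_logrank

        df = _records(times, list(map(bool, events)), groups)
        hi = df[df.group == "high"]
        lo = df[df.group == "low"]
        ll = ll_logrank(hi.time, lo.time, hi.event, lo.event)
        assert logrank_test(df).statistic == pytest.approx(ll.test_statistic, rel=1e-9)

    def test_identical_groups_give_null_result(self):
        df = _records([1, 2, 3] * 2, [True] * 6, ["high"] * 3 + ["low"] * 3)
        result = logrank_test(df)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.hazard_ratio == pytest.approx(1.0)
        assert result.ci_low < 1.0 < result.ci_high

    def test_ci_brackets_hazard_ratio(self, rng):
        t = rng.exponential(10, 40)
        df = _records(t, [True] * 40, ["high"] * 20 + ["low"] * 20)
        r = logrank_test(df)
        assert r.ci_low <= r.hazard_ratio <= r.ci_high
        assert 0 <= r.p_value <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1, 2], [True, True], ["high", "high"]))

    def test_null_permutation_p_uniform(self, rng):
        """Permuting labels under the null gives uniform p-values."""
        t = rng.exponential(10, 50)
        e = rng.random(50) > 0.2
        ps = []
        for _ in range(1000):
            g = np.where(rng.permutation(50) < 25, "high", "low")
            ps.append(logrank_test(_records(t, e, g)).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCox:
    def test_covariate_free_fit_matches_logrank_hr_small_effect(self, rng):
        # O/E and Cox estimators coincide as the effect shrinks
        n = 2000
        grp = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        lam = 0.02 * np.exp(np.log(0.95) * grp)
        df = _records(rng.exponential(1 / lam), [True] * n, np.where(grp, "high", "low"))
        lr = logrank_test(df)
        cx, _ = cox_multivariate(df, covariates=[])
        assert np.log(cx.hazard_ratio) == pytest.approx(np.log(lr.hazard_ratio), abs=1e-3)

    def test_constant_group_rejected(self):
        df = _records([1, 2, 3], [True] * 3, ["high"] * 3)
        with pytest.raises(ValueError, match="variation"):
            cox_multivariate(df, covariates=[])

    def test_categorical_covariates_dummy_coded(self, rng):
        n = 120
        df = _records(
            rng.exponential(20, n),
            [True] * n,
            rng.choice(["high", "low"], n),
            age_category=rng.choice(["<40", "40-49", "50-59", ">60"], n),
            t_stage=rng.choice([1, 2, 3, 4], n),
            n_status=rng.choice(["negative", "positive"], n),
        )
        result, per_cov = cox_multivariate(df)
        # 3 age + 3 stage + 1 nodal dummies against first levels
        assert len(per_cov) == 7
        assert result.ci_low <= result.hazard_ratio <= result.ci_high

    def test_unknown_covariate_level_rejected(self):
        df = _records(
            [1, 2, 3, 4], [True] * 4, ["high", "low"] * 2, t_stage=[1, 2, 9, 1]
        )
        with pytest.raises(ValueError, match="unknown levels"):
            cox_multivariate(df, covariates=["t_stage"])


class TestInteractionLrt:
    @staticmethod
    def _simulate(rng, n, hr_a, hr_b):
        grp = rng.random(n) < 0.5
        mod = rng.random(n) < 0.5
        loghr = np.where(mod, np.log(hr_b), np.log(hr_a)) * grp
        t = rng.exponential(1 / (0.02 * np.exp(loghr)))
        return _records(
            t, [True] * n, np.where(grp, "high", "low"), er_status=np.where(mod, "pos", "neg")
        )

    def test_no_interaction_requested_gives_null(self, rng):
        df = self._simulate(rng, 80, 0.5, 0.5)
        out = interaction_lrt(df, "er_status", include_interaction=False)
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_null_p_uniform_over_simulations(self, rng):
        ps = [
            interaction_lrt(self._simulate(rng, 150, 0.5, 0.5), "er_status")["p_value"]
            for _ in range(100)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_opposite_effects_detected(self, rng):
        hits = sum(
            interaction_lrt(self._simulate(rng, 400, 0.4, 2.5), "er_status")["p_value"] < 0.05
            for _ in range(50)
        )
        assert hits >= 0.8 * 50

    def test_modifier_level_missing_group_rejected(self):
        df = _records(
            [1, 2, 3, 4], [True] * 4, ["high", "high", "low", "low"],
            er_status=["pos", "pos", "neg", "neg"],
        )
        with pytest.raises(ValueError, match="both groups"):
            interaction_lrt(df, "er_status")


class TestSpearmanBH:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        rho, _ = spearman_bh(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_bh_adjustment_closed_form(self, rng):
        # 4 variables -> 6 pairwise tests; check BH against the step-up formula
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        rho, padj = spearman_bh(df)
        praw = np.array(
            [
                stats.spearmanr(df[c1], df[c2]).pvalue
                for i, c1 in enumerate(df.columns)
                for c2 in df.columns[i + 1:]
            ]
        )
        m = len(praw)
        order = np.argsort(praw)
        stepup = np.minimum.accumulate((praw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepup, 1.0)
        got = padj.to_numpy()[np.triu_indices(4, 1)]
        assert np.allclose(got, expected)

    def test_bh_monotone_and_bounded(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        _, padj = spearman_bh(df)
        vals = padj.to_numpy()[np.triu_indices(5, 1)]
        assert (vals <= 1.0 + 1e-12).all() and (vals >= 0).all()

    def test_constant_variable_flagged_nan(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        rho, padj = spearman_bh(df)
        assert np.isnan(rho.loc["a", "b"])
        assert np.isnan(padj.loc["a", "b"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            spearman_bh(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestRobustZscore:
    def test_closed_form_row(self):
        z, flagged = robust_zscore(np.array([[1.0, 2.0, 3.0]]), axis=1)
        assert z[0] == pytest.approx([-0.6745, 0.0, 0.6745], abs=1e-4)
        assert not flagged.any()

    def test_constant_row_flagged_zeros(self):
        z, flagged = robust_zscore(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]]), axis=1)
        assert flagged.tolist() == [True, False]
        assert np.allclose(z[0], 0.0)

    @given(
        st.floats(0.01, 100.0),
        st.floats(-50.0, 50.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, scale, shift):
        row = np.array([[0.3, 1.7, 2.9, -4.0, 0.0]])
        z1, _ = robust_zscore(row, axis=1)
        z2, _ = robust_zscore(row * scale + shift, axis=1)
        assert np.allclose(z1, z2, atol=1e-8)
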