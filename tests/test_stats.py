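import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caficu as cf
from caficu.errors import InsufficientDataError
from caficu.stats import (
    RiskTier,
    classify_risk_tier,
    km_curve,
    reclassification,
    roc_youden,
    sample_size_epv,
)


def cohort_from_counts(n_dead, n_total, seed=0):
    """Cohort under the 30-day endpoint convention: deaths carry their day,
    everyone else is censored at day 30."""
    rng = np.random.default_rng(seed)
    times = np.concatenate([
        rng.integers(1, 31, n_dead).astype(float),
        np.full(n_total - n_dead, 30.0),
    ])
    events = np.concatenate([np.ones(n_dead), np.zeros(n_total - n_dead)])
    return times, events


class TestKaplanMeier:
    def test_mortality_equals_death_proportion_without_early_censoring(self):
        times, events = cohort_from_counts(83, 375)
        km = km_curve(times, events)
        assert km.mortality_at(30.0) == pytest.approx(83 / 375, abs=1e-12)

    def test_no_events_survival_one_se_zero(self):
        km = km_curve(np.full(50, 30.0), np.zeros(50))
        assert km.survival_at(30.0) == 1.0
        assert km.n_events == 0

    def test_identical_groups_logrank_p_one(self):
        times, events = cohort_from_counts(20, 100)
        t2 = np.concatenate([times, times])
        e2 = np.concatenate([events, events])
        g = np.concatenate([np.zeros(100), np.ones(100)])
        _, p = km_curve(t2, e2, group=g)
        assert p == pytest.approx(1.0)

    def test_survival_monotone_nonincreasing_and_ci_clipped(self):
        times, events = cohort_from_counts(40, 120, seed=3)
        km = km_curve(times, events)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.ci_low >= 0) & (km.ci_high <= 1))
        assert np.all(km.ci_low <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_high + 1e-12)

    def test_matches_lifelines(self):
        """Independent cross-check of the product-limit curve and its CI."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        times = rng.exponential(20, 300).clip(0.1, 30.0)
        events = rng.random(300) < 0.6
        km = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [5.0, 15.0, 29.0]:
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )
        # exponential-Greenwood CI agrees at event times
        ci = kmf.confidence_interval_survival_function_
        idx = np.searchsorted(ci.index.to_numpy(), km.times)
        assert np.allclose(km.ci_low, ci.iloc[idx, 0].to_numpy(), atol=1e-6)

    def test_greenwood_variance_closed_form_single_event(self):
        # 4 subjects, one death at t=10: S=3/4, Var = S^2 * 1/(4*3)
        km = km_curve([10.0, 30.0, 30.0, 30.0], [1, 0, 0, 0])
        assert km.survival[0] == pytest.approx(0.75)
        assert km.greenwood_se[0] == pytest.approx(0.75 * np.sqrt(1 / 12))

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            km_curve([], [])


class TestCox:
    def test_two_sample_exponential_matches_rate_ratio(self):
        """No censoring, binary covariate: the Cox HR approaches the
        closed-form event-rate ratio of the two exponential samples."""
        rng = np.random.default_rng(21)
        n = 2000
        x = np.repeat([0, 1], n // 2)
        lam = np.where(x == 1, 0.3, 0.1)
        t = rng.exponential(1 / lam)
        df = pd.DataFrame({"time_days": t, "event": 1, "x": x})
        fit = cf.fit_cox(df, ["x"])
        rate_ratio = (np.sum(x == 1) / t[x == 1].sum()) / (np.sum(x == 0) / t[x == 0].sum())
        assert fit.hr["x"] == pytest.approx(rate_ratio, rel=0.10)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_days": [1.0, 2, 3], "event": [1, 0, 1], "x": [1.0, 1, 1]})
        with pytest.raises(InsufficientDataError):
            cf.fit_cox(df, ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_days": [30.0] * 5, "event": [0] * 5, "x": np.arange(5.0)})
        with pytest.raises(InsufficientDataError):
            cf.fit_cox(df, ["x"])

    def test_derive_score_coefficients_signs(self):
        df, _ = cf.simulate_cohort(
            cf.CohortSimConfig(n=3000, beta_prd=0.05, beta_dc=-0.2, seed=13)
        )
        df = df.rename(columns={"prd_capped": "prd_c", "dc_capped": "dc_c"})
        coef = cf.derive_score_coefficients(df, prd_col="prd_c", dc_col="dc_c")
        assert coef.beta_prd > 0 > coef.beta_dc
        assert coef.beta_dc_uni < 0


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.youden_j == 1.0

    def test_four_point_toy_threshold_between_2_and_3(self):
        r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == 1.0
        assert 2 < r.threshold < 3

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 4000)
        outcomes = rng.random(4000) < 0.3
        assert roc_youden(scores, outcomes).auc == pytest.approx(0.5, abs=0.05)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 1000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 200)
        outcomes = rng.random(200) < 0.4
        if outcomes.all() or not outcomes.any():
            return
        a = roc_youden(scores, outcomes).auc
        b = roc_youden(np.exp(scores * 2) + 5, outcomes).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_youden([1, 2, 3], [1, 1, 1])


class TestReclassification:
    def test_identical_models_give_zeros(self):
        df, truth = cf.simulate_cohort(cf.CohortSimConfig(n=500, seed=2))
        lp = truth["linear_predictor"]
        r = reclassification(lp, lp, df["time_days"], df["event"], n_boot=0)
        assert r.idi == 0.0
        assert r.nri_continuous == 0.0
        assert r.median_improvement == 0.0

    def test_adding_true_predictor_positive_idi(self):
        df, truth = cf.simulate_cohort(
            cf.CohortSimConfig(n=1500, beta_prd=0.08, beta_dc=-0.3, seed=4)
        )
        base = df["saps3"].to_numpy(float) * 0.02
        aug = base + truth["linear_predictor"]
        r = reclassification(base, aug, df["time_days"], df["event"], n_boot=100, seed=0)
        assert r.idi > 0
        assert r.ci["idi"][0] > 0  # bootstrap CI excludes zero

    def test_precomputed_risks_accepted(self):
        rng = np.random.default_rng(8)
        d = rng.random(400) < 0.2
        base = np.clip(0.2 + rng.normal(0, 0.05, 400), 0, 1)
        aug = np.clip(base + 0.3 * d - 0.05, 0, 1)
        r = reclassification(
            base, aug, np.where(d, 10.0, 30.0), d, scores_are_risks=True, n_boot=0
        )
        assert r.idi > 0.2

    def test_one_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            reclassification([1, 2], [1, 2], [30.0, 30.0], [0, 0], n_boot=0)


class TestRiskTiers:
    @pytest.mark.parametrize(
        "saps3,caf,tier",
        [
            (50, 40, RiskTier.LOW),
            (55.9, 100, RiskTier.LOW),
            (56, 0, RiskTier.INCREASED),
            (70, 5, RiskTier.INCREASED),
            (95, 3, RiskTier.INCREASED),
            (69, 11, RiskTier.HIGH),
            (88, 99, RiskTier.HIGH),
            (89, 11, RiskTier.VERY_HIGH),
            (120, 100, RiskTier.VERY_HIGH),
        ],
    )
    def test_published_partition(self, saps3, caf, tier):
        assert classify_risk_tier(saps3, caf) is tier

    def test_partition_is_total_and_exclusive(self):
        """Exactly one tier fires everywhere on a dense (saps3, caf) grid."""
        for saps3 in np.linspace(0, 150, 151):
            for caf in np.linspace(0, 100, 51):
                tier = classify_risk_tier(saps3, caf)
                assert isinstance(tier, RiskTier)

    def test_alias_names(self):
        assert RiskTier.LOW.alias == "very_low"
        assert RiskTier.VERY_HIGH.alias == "high"


class TestSampleSizeEpv:
    @pytest.mark.parametrize(
        "n_params,rate,expected",
        [(3, 0.10, (30, 300)), (1, 1.0, (10, 10)), (2, 0.25, (20, 80))],
    )
    def test_epv_arithmetic(self, n_params, rate, expected):
        assert sample_size_epv(n_params, rate) == expected

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_size_epv(3, 0.0)
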