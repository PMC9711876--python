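"""Clinical endpoints: response rule, survival, tests, and trial formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arascore import clinical_stats as cs
from arascore.synthetic_data import CohortSimConfig, generate_clinical_table

from helpers import manual_logrank_statistic, manual_product_limit


class TestPercentChange:
    @pytest.mark.parametrize("pre,on,expected", [(100, 40, -60), (10, 10, 0), (8, 12, 50)])
    def test_examples(self, pre, on, expected):
        assert cs.percent_change(pre, on) == pytest.approx(expected)

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError):
            cs.percent_change(0, 5)


class TestClassifyResponse:
    def test_psa_boundary_is_inclusive(self):
        responder, _ = cs.classify_response(100, 50)  # exactly -50%
        assert responder

    def test_volume_rescues_via_or_rule(self):
        responder, used = cs.classify_response(100, 80, 1000, 650)  # -20% PSA, -35% vol
        assert responder and used

    def test_neither_criterion_met(self):
        responder, _ = cs.classify_response(100, 80, 1000, 900)
        assert not responder

    def test_missing_volume_is_psa_only(self):
        responder, used = cs.classify_response(100, 30)
        assert responder and not used

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pre=st.floats(1, 1000), on=st.floats(0, 1000), drop=st.floats(0, 100))
    def test_lower_on_treatment_psa_never_unresponds(self, pre, on, drop):
        before, _ = cs.classify_response(pre, on)
        after, _ = cs.classify_response(pre, max(on - drop, 0.0))
        assert after or not before


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = cs.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.times, [1, 2, 3])

    def test_all_censored_is_flat_one(self):
        curve = cs.km_estimate([1, 2, 3], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_mixed_toy_matches_hand_product_limit(self):
        times, events = [1, 2, 3], [1, 0, 1]
        curve = cs.km_estimate(times, events)
        oracle = manual_product_limit(times, events)
        assert curve.probability_at(1) == pytest.approx(oracle[1])  # 2/3
        assert curve.probability_at(3) == pytest.approx(oracle[3])  # 0
        assert oracle[1] == pytest.approx(2 / 3) and oracle[3] == 0.0

    def test_random_censored_data_matches_hand_oracle(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=40).round(1)
        events = rng.random(40) < 0.7
        curve = cs.km_estimate(times, events)
        for t, s in manual_product_limit(times, events).items():
            assert curve.probability_at(t) == pytest.approx(s)

    def test_survival_curve_invariants(self):
        rng = np.random.default_rng(1)
        curve = cs.km_estimate(rng.exponential(5, 30), rng.random(30) < 0.5)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()
        assert curve.probability_at(-1) == 1.0  # S(0) = 1

    def test_errors(self):
        with pytest.raises(ValueError):
            cs.km_estimate([], [])
        with pytest.raises(ValueError):
            cs.km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        stat, p = cs.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_risk_table_oracle(self):
        ta, ea = [1, 3, 5, 7, 9], [1, 1, 0, 1, 1]
        tb, eb = [2, 4, 6, 8, 10], [1, 0, 1, 1, 0]
        stat, _ = cs.logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(manual_logrank_statistic(ta, ea, tb, eb), rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(5, 20), rng.exponential(10, 20)
        ea = eb = np.ones(20, dtype=bool)
        s1, _ = cs.logrank_test(ta, ea, tb, eb)
        s2, _ = cs.logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)

    def test_planted_hazard_ratio_detected_with_power(self):
        rejections = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            ta = rng.exponential(1.0, 50)       # hazard 1
            tb = rng.exponential(3.0, 50)       # hazard 1/3
            _, p = cs.logrank_test(ta, np.ones(50), tb, np.ones(50))
            rejections += p < 0.05
        assert rejections >= 80

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            cs.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestGroupComparisons:
    def test_paired_identity_gives_zero(self):
        x = [1.0, 2.0, 3.0]
        stat, p = cs.paired_and_group_tests(x, x, mode="paired")
        assert stat == 0.0 and p == 1.0

    def test_welch_matches_textbook_arithmetic(self):
        x, y = [10.0, 12.0, 14.0], [1.0, 2.0, 3.0, 4.0]
        # hand computation of the Welch statistic and df
        mx, my = 12.0, 2.5
        vx = sum((v - mx) ** 2 for v in x) / 2
        vy = sum((v - my) ** 2 for v in y) / 3
        se2 = vx / 3 + vy / 4
        t_hand = (mx - my) / math.sqrt(se2)
        df_hand = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 4) ** 2 / 3)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        stat, p = cs.paired_and_group_tests(x, y, mode="welch")
        assert stat == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_chi2_identical_proportions_is_zero(self):
        stat, p = cs.paired_and_group_tests((5, 10), (10, 20), mode="chi2")
        assert stat == pytest.approx(0.0)

    def test_insufficient_n_errors(self):
        with pytest.raises(ValueError):
            cs.paired_and_group_tests([1.0], [2.0], mode="welch")
        with pytest.raises(ValueError):
            cs.paired_and_group_tests([1.0, 2.0], [1.0], mode="paired")


def test_bh_adjustment_is_monotone_and_optional():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = cs.adjust_pvalues(p)
    assert (adj >= np.asarray(p)).all()
    assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
    with pytest.raises(ValueError):
        cs.adjust_pvalues(p, method="bonferroni")


class TestPearson:
    def test_affine_and_antithetic(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cs.pearson_correlation(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert cs.pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_five_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_hand = cov / (x.std() * y.std())
        assert cs.pearson_correlation(x, y)[0] == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            cs.pearson_correlation([1, 1, 1], [1, 2, 3])


class TestTrialFormulas:
    def test_caliper_volume_unit_cube(self):
        assert cs.tumor_volume(1, 1, 1) == pytest.approx(0.5236)

    def test_caliper_volume_scales_linearly(self):
        assert cs.tumor_volume(2, 1, 1) == pytest.approx(1.0472)

    def test_coefficient_matches_sphere_formula(self):
        d = 3.7
        exact = math.pi / 6 * d**3
        assert abs(cs.tumor_volume(d, d, d) - exact) / exact < 2e-5

    def test_nonpositive_dimension_errors(self):
        with pytest.raises(ValueError):
            cs.tumor_volume(0, 1, 1)

    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 18, 20, 18), 1.0), ((20, 18, 22, 18), 4.0), ((21, 18, 20, 18), 0.5)],
    )
    def test_ddct_fold_change(self, cts, expected):
        assert cs.ddct_relative_expression(*cts) == pytest.approx(expected)

    def test_ddct_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            cs.ddct_relative_expression(np.nan, 18, 20, 18)

    def test_predicted_population_response(self):
        assert cs.predicted_population_response(36.5, 70) == 25.6
        assert cs.predicted_population_response(100, 42.5) == 42.5
        assert cs.predicted_population_response(0, 70) == 0.0

    def test_predicted_population_response_rounds_half_up(self):
        assert cs.predicted_population_response(50, 51.1) == 25.6  # 25.55 -> 25.6

    def test_predicted_population_response_range_check(self):
        with pytest.raises(ValueError):
            cs.predicted_population_response(120, 70)


class TestStratification:
    def _records(self, scores, responders, n_months=None):
        n = len(scores)
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "psa_pre": 100.0,
            "psa_on": [30.0 if r else 90.0 for r in responders],
            "rpfs_months": n_months if n_months is not None else rng.exponential(10, n),
            "rpfs_event": 1,
            "os_months": n_months if n_months is not None else rng.exponential(20, n),
            "os_event": 1,
            "arawm_score": scores,
        })

    def test_strict_cutoff_boundary(self):
        rec = self._records([0.61, 0.60], [True, False])
        strat = cs.stratify_by_biomarker(rec, cutoff=0.6)
        assert len(strat.high) == 1 and len(strat.low) == 1

    def test_single_stratum_warns_and_skips_comparisons(self):
        rec = self._records([0.9, 0.8], [True, True])
        strat = cs.stratify_by_biomarker(rec, cutoff=0.6)
        assert strat.warnings and strat.response_chi2 is None

    def test_planted_response_enrichment_detected(self):
        cfg = CohortSimConfig(n_samples=60, seed=9)
        truth = pd.DataFrame({
            "sample_id": [f"p{i}" for i in range(60)],
            "ar_high": [i < 25 for i in range(60)],
        })
        table = generate_clinical_table(truth, cfg)
        table["arawm_score"] = np.where(truth["ar_high"], 0.8, 0.4)
        strat = cs.stratify_by_biomarker(table, cutoff=0.6)
        assert strat.responder_proportions["high"] > strat.responder_proportions["low"]
        assert strat.response_chi2[1] < 0.05
        assert set(strat.logrank) == {"rpfs", "os"}

    def test_missing_scores_error(self):
        rec = self._records([0.7, 0.5], [True, False]).drop(columns=["arawm_score"])
        with pytest.raises(ValueError, match="score"):
            cs.stratify_by_biomarker(rec)
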