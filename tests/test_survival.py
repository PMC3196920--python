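"""Median split, Kaplan-Meier, log-rank, clinical summaries, survival screen."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from inflamsig.io import GeneList
from inflamsig.survival import (
    clinical_summary,
    event_indicator,
    km_estimate,
    logrank_test,
    median_split,
    survival_inputs_for_gene,
    survival_screen,
)
from inflamsig.synthetic import SimConfig, simulate_clinical, simulate_expression

from conftest import surv_inputs


class TestMedianSplit:
    def test_even_cohort_midpoint(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_44_distinct_values_split_evenly(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.permutation(44).astype(float))
        labels = median_split(values)
        assert (labels == "high").sum() == 22
        assert (labels == "low").sum() == 22

    def test_ties_at_median_go_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 2.0, 2.0, 3.0, 4.0]))
        # median = 2; the three 2s are ties and go low
        assert (labels == "low").sum() == 4
        assert (labels == "high").sum() == 2

    def test_constant_vector_is_hard_error(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.Series([3.0] * 10))


class TestKaplanMeier:
    def test_single_subject_event(self):
        curve = km_estimate(surv_inputs([5.0], [True]))
        assert curve.event_times.tolist() == [5.0]
        assert curve.survival.tolist() == [0.0]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(surv_inputs([3.0, 7.0, 9.0], [False, False, False]))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_matches_lifelines_to_machine_precision(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(30, size=30).round(1)  # rounding forces ties
        e = rng.uniform(size=30) < 0.7
        curve = km_estimate(surv_inputs(t, e))
        ref = KaplanMeierFitter().fit(t, e).survival_function_at_times(curve.event_times)
        assert np.allclose(curve.survival, ref.to_numpy(), atol=1e-12)

    def test_order_invariant_and_monotone(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(20, size=25)
        e = rng.uniform(size=25) < 0.6
        a = km_estimate(surv_inputs(t, e))
        perm = rng.permutation(25)
        b = km_estimate(surv_inputs(t[perm], e[perm]))
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.survival, b.survival)
        assert np.all(np.diff(a.survival) <= 1e-15)
        assert np.all(np.diff(a.at_risk) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            surv_inputs([-1.0], [True])


class TestLogRank:
    def test_identical_groups_null(self):
        g = surv_inputs([2.0, 4.0, 6.0], [True, True, False])
        chi2, p = logrank_test(g, surv_inputs([2.0, 4.0, 6.0], [True, True, False], "low"))
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_six_subject_table(self):
        # group A events at 1, 3; censored at 5.  group B events at 2, 4, 6.
        # t=1: n=(3,3) d_A=1 -> e=0.5, v=0.25
        # t=2: n=(2,3) d_B=1 -> e=0.4, v=0.24
        # t=3: n=(2,2) d_A=1 -> e=0.5, v=0.25
        # t=4: n=(1,2) d_B=1 -> e=1/3, v=2/9
        # t=6: n=(0,1) d_B=1 -> e=0,   v=0
        # O-E = 2 - (0.5+0.4+0.5+1/3) = 0.2667, V = 0.9622
        a = surv_inputs([1.0, 3.0, 5.0], [True, True, False], "high")
        b = surv_inputs([2.0, 4.0, 6.0], [True, True, True], "low")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx((0.26666666666666666**2) / 0.9622222222222222, rel=1e-9)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(19)
        t1 = rng.exponential(30, 25).round(0)
        t2 = rng.exponential(15, 20).round(0)
        e1 = rng.uniform(size=25) < 0.7
        e2 = rng.uniform(size=20) < 0.7
        chi2, p = logrank_test(surv_inputs(t1, e1), surv_inputs(t2, e2, "low"))
        ref = lifelines_logrank(t1, t2, e1, e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(23)
        a = surv_inputs(rng.exponential(30, 15), rng.uniform(size=15) < 0.8)
        b = surv_inputs(rng.exponential(10, 15), rng.uniform(size=15) < 0.8, "low")
        chi_ab, p_ab = logrank_test(a, b)
        chi_ba, p_ba = logrank_test(b, a)
        assert chi_ab == pytest.approx(chi_ba, rel=1e-12)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_zero_events_is_hard_error(self):
        a = surv_inputs([1.0, 2.0], [False, False])
        b = surv_inputs([3.0, 4.0], [False, False], "low")
        with pytest.raises(ValueError, match="event"):
            logrank_test(a, b)

    def test_power_at_hazard_ratio_three(self):
        # hazard ratio 3, 22 + 22 subjects, ~60% events: empirical power
        # of the unweighted log-rank is ~0.83, so 20 replicates must
        # reject at 0.05 in at least three quarters of them
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng([seed, 99])
            t1, t2 = rng.exponential(120, 22), rng.exponential(40, 22)
            c1, c2 = rng.uniform(0, 150, 22), rng.uniform(0, 150, 22)
            g1 = surv_inputs(np.minimum(t1, c1), t1 <= c1)
            g2 = surv_inputs(np.minimum(t2, c2), t2 <= c2, "low")
            hits += logrank_test(g1, g2)[1] < 0.05
        assert hits >= 15


class TestClinicalSummary:
    def test_published_cohort_statistics(self, clinical_records):
        s = clinical_summary(clinical_records)
        assert s.n == 44
        assert s.mean_age == pytest.approx(17.9, abs=0.05)
        assert s.mean_efs == pytest.approx(40.1, abs=0.05)
        assert s.mean_ovs == pytest.approx(57.0, abs=0.05)
        assert s.median_followup == pytest.approx(44.8, abs=1e-9)
        assert s.male_to_female == pytest.approx(1.75, abs=1e-9)

    def test_single_record(self, clinical_records):
        r = clinical_records[0]
        s = clinical_summary([r])
        assert s.mean_age == r.age and s.mean_ovs == r.ovs and s.median_followup == r.ovs

    def test_event_indicator_reconstruction(self, clinical_records):
        by = {r.sample_code: r for r in clinical_records}
        # died with efs == ovs: event for both endpoints
        assert event_indicator(by["R29"], "OVS") == (4.6, True)
        assert event_indicator(by["R29"], "EFS") == (4.6, True)
        # alive, relapse before last follow-up: censored OVS, event EFS
        assert event_indicator(by["R34"], "OVS") == (56.5, False)
        assert event_indicator(by["R34"], "EFS") == (19.4, True)
        # alive, no event: censored both
        assert event_indicator(by["R41"], "OVS") == (125.1, False)
        assert event_indicator(by["R41"], "EFS") == (125.1, False)


class TestSurvivalScreen:
    def _study(self, seed=0, beta=-1.0):
        config = SimConfig(
            seed=seed, n_genes=200, n_inflammation_list=50,
            prognostic_genes={"G0001": beta},
        )
        expr, _ = simulate_expression(config)
        clinical = simulate_clinical(config, expr)
        return expr.subset_groups(["patient"]), clinical

    def test_engineered_separation_gives_small_p(self, clinical_records):
        # gene expression ordered exactly by survival time: perfect separation
        import pandas as pd
        from inflamsig.io import ExpressionMatrix

        codes = [r.sample_code for r in clinical_records]
        ovs_order = np.argsort([r.ovs for r in clinical_records])
        values = np.empty(44)
        values[ovs_order] = np.arange(44, dtype=float)
        data = pd.DataFrame([values], index=["SEP"], columns=codes)
        expr = ExpressionMatrix(data, pd.Series("patient", index=codes))
        table = survival_screen(expr, GeneList("l", ["SEP"]), clinical_records, "OVS")
        assert table.loc[0, "p"] < 1e-4

    def test_moderate_protective_gene_ranks_near_top(self):
        # a per-SD hazard ratio of 2.5 is reliably near the top of the
        # 32-gene screen at n = 44, though not always rank one
        genes = GeneList("screen", ["G0001"] + [f"G{i:04d}" for i in range(2, 33)])
        top5 = 0
        for seed in range(5):
            expr, clinical = self._study(seed=seed, beta=-np.log(2.5))
            table = survival_screen(expr, genes, clinical, "OVS")
            top5 += table["gene"].tolist().index("G0001") < 5
        assert top5 >= 4

    def test_mismatched_sample_ids_error(self):
        expr, clinical = self._study()
        clipped = clinical[:-1]
        with pytest.raises(ValueError, match=expr.sample_ids[-1]):
            survival_inputs_for_gene(expr.data.iloc[0], clipped, "OVS")

    def test_all_censored_cohort_raises_for_every_gene(self):
        config = SimConfig(seed=1, n_genes=50, n_inflammation_list=20, censor_rate=1.0)
        expr, _ = simulate_expression(config)
        clinical = simulate_clinical(config, expr)
        patients = expr.subset_groups(["patient"])
        with pytest.raises(ValueError, match="event"):
            survival_screen(patients, GeneList("l", ["G0001"]), clinical, "OVS")
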