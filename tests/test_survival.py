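import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter

from damil.bags import NRC, RC
from damil.survival import (
    CoxResult,
    aggregate_patient,
    apply_admin_censoring,
    chi_square_assoc,
    classification_metrics,
    cox_univariate,
    fold_metrics_report,
    km_table,
    label_predicted_groups,
)
from damil.synthetic import SyntheticCohortSpec, gen_cohort


def survival_frame(times, events, groups):
    return pd.DataFrame(
        {"time_months": times, "event": events, "group": groups}
    )


def simulated_groups(seed, n=2000, hr=2.3):
    spec = SyntheticCohortSpec(
        n_rc=n // 2, n_nrc=n // 2, dim=2, n_instances=(1, 1), true_hr=hr, seed=seed
    )
    _, cohort = gen_cohort(spec)
    cohort = cohort.copy()
    cohort["group"] = np.where(cohort["label"] == RC, "high", "low")
    return cohort


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = classification_metrics(
            np.array([0.9, 0.8, 0.1, 0.2]), [RC, RC, NRC, NRC]
        )
        assert m.auroc == 100.0 and m.accuracy == 100.0
        assert m.sensitivity == 100.0 and m.specificity == 100.0

    def test_all_predicted_nrc(self):
        m = classification_metrics(np.array([0.1, 0.2, 0.3, 0.4]), [NRC, NRC, RC, RC])
        assert m.specificity == 100.0 and m.sensitivity == 0.0

    def test_matches_pairwise_auroc_oracle(self, rng):
        """Oracle: O(n^2) pair enumeration with ties counting one half."""
        scores = rng.integers(0, 5, size=20) / 4.0  # force ties
        labels = [RC if rng.random() < 0.5 else NRC for _ in range(20)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = RC, NRC
        m = classification_metrics(scores, labels)
        pos = [s for s, l in zip(scores, labels) if l == RC]
        neg = [s for s, l in zip(scores, labels) if l == NRC]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert abs(m.auroc - 100.0 * wins / (len(pos) * len(neg))) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            classification_metrics(np.array([0.1, 0.9]), [RC, RC])

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        labels = [RC] * 6 + [NRC] * 6
        a = classification_metrics(scores, labels).auroc
        b = classification_metrics(np.exp(3 * scores) + 1, labels).auroc
        assert abs(a - b) < 1e-9

    def test_fold_report_mean_sd(self):
        preds = pd.DataFrame(
            {
                "fold": [0, 0, 0, 0, 1, 1, 1, 1],
                "p_RC": [0.9, 0.8, 0.1, 0.2, 0.7, 0.4, 0.6, 0.3],
                "label": [RC, RC, NRC, NRC] * 2,
            }
        )
        report = fold_metrics_report(preds)
        assert set(report["per_fold"]) == {0, 1}
        vals = [report["per_fold"][f]["auroc"] for f in (0, 1)]
        assert abs(report["summary"]["auroc"]["mean"] - np.mean(vals)) < 1e-9
        assert abs(report["summary"]["auroc"]["sd"] - np.std(vals, ddof=1)) < 1e-9


class TestAggregatePatient:
    def frame(self):
        return pd.DataFrame(
            {
                "patient_id": ["a", "b", "b"],
                "slide_id": ["s1", "s2", "s3"],
                "p_RC": [0.4, 0.2, 0.9],
            }
        )

    def test_single_slide_identity(self):
        agg = aggregate_patient(self.frame())
        assert float(agg.loc[agg["patient_id"] == "a", "score"].iloc[0]) == 0.4

    def test_max_rule(self):
        agg = aggregate_patient(self.frame())
        assert float(agg.loc[agg["patient_id"] == "b", "score"].iloc[0]) == 0.9
        assert agg.loc[agg["patient_id"] == "b", "group"].iloc[0] == "high"

    def test_mean_rule(self):
        agg = aggregate_patient(self.frame(), rule="mean")
        assert abs(float(agg.loc[agg["patient_id"] == "b", "score"].iloc[0]) - 0.55) < 1e-12

    def test_slide_order_invariance(self):
        shuffled = self.frame().iloc[[2, 0, 1]].reset_index(drop=True)
        a = aggregate_patient(self.frame()).sort_values("patient_id").reset_index(drop=True)
        b = aggregate_patient(shuffled).sort_values("patient_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_rule(self):
        with pytest.raises(ValueError):
            aggregate_patient(self.frame(), rule="median")


class TestCoxUnivariate:
    def test_identical_groups_give_hr_one(self):
        times = [5.0, 10.0, 20.0, 30.0, 40.0]
        events = [1, 1, 0, 1, 0]
        df = survival_frame(times * 2, events * 2, ["low"] * 5 + ["high"] * 5)
        res = cox_univariate(df)
        assert abs(res.hr - 1.0) < 1e-6

    def test_recovers_true_hr(self):
        res = cox_univariate(simulated_groups(seed=7))
        assert 2.0 <= res.hr <= 2.65
        assert res.converged

    def test_matches_lifelines_oracle(self):
        """Oracle: independent reference fitter (Breslow) on the same draw."""
        df = simulated_groups(seed=13, n=600)
        res = cox_univariate(df)
        ldf = df[["time_months", "event"]].copy()
        ldf["x"] = (df["group"] == "high").astype(int)
        cph = CoxPHFitter(baseline_estimation_method="breslow").fit(
            ldf, "time_months", "event"
        )
        assert abs(res.beta - float(cph.params_["x"])) < 1e-4
        assert abs(res.se - float(cph.standard_errors_["x"])) < 1e-4

    def test_ci_brackets_hr(self):
        res = cox_univariate(simulated_groups(seed=3, n=400))
        assert res.ci_low <= res.hr <= res.ci_high
        assert abs(res.hr - np.exp(res.beta)) < 1e-12

    def test_no_events_rejected(self):
        df = survival_frame([1.0, 2.0], [0, 0], ["low", "high"])
        with pytest.raises(ValueError, match="no events"):
            cox_univariate(df)

    def test_single_group_rejected(self):
        df = survival_frame([1.0, 2.0], [1, 1], ["high", "high"])
        with pytest.raises(ValueError, match="no subjects"):
            cox_univariate(df)

    def test_monotone_likelihood_flagged(self):
        # all events in one arm, none in the other -> beta diverges
        df = survival_frame(
            [1.0, 2.0, 3.0, 60.0, 60.0, 60.0],
            [1, 1, 1, 0, 0, 0],
            ["high"] * 3 + ["low"] * 3,
        )
        res = cox_univariate(df)
        assert not res.converged

    def test_admin_censoring_applied(self):
        df = survival_frame([50.0, 70.0, 80.0, 90.0], [1, 1, 1, 1], ["high", "high", "low", "low"])
        out = apply_admin_censoring(df, 60.0)
        assert out["time_months"].max() == 60.0
        assert out["event"].sum() == 1

    def test_permuted_labels_concentrate_at_null(self):
        """Cox on permuted groups has median HR near 1 over 50 permutations."""
        df = simulated_groups(seed=5, n=400)
        rng = np.random.default_rng(0)
        hrs = []
        for _ in range(50):
            perm = df.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            hrs.append(cox_univariate(perm).hr)
        assert 0.8 <= float(np.median(hrs)) <= 1.25

    def test_parameter_recovery_across_seeds(self):
        hrs = [cox_univariate(simulated_groups(seed=200 + s)).hr for s in range(20)]
        assert abs(np.mean(hrs) - 2.3) / 2.3 < 0.10


class TestKmTable:
    def test_no_events_flat_at_one(self):
        df = survival_frame([10.0, 20.0, 30.0], [0, 0, 0], ["low"] * 3)
        km = km_table(df)
        assert (km["survival"] == 1.0).all()

    def test_single_event_drop(self):
        df = survival_frame([10.0, 20.0, 30.0, 40.0], [0, 1, 0, 0], ["low"] * 4)
        km = km_table(df)
        assert km["survival"].iloc[-1] == pytest.approx(2.0 / 3.0)  # 3 at risk at t=20

    def test_starts_at_one_and_monotone(self):
        df = simulated_groups(seed=9, n=200)
        km = km_table(df)
        for _, grp in km.groupby("group"):
            assert grp["survival"].iloc[0] == 1.0
            assert (np.diff(grp["survival"]) <= 1e-12).all()

    def test_matches_hand_computed_product(self):
        """Oracle: explicit product over event times."""
        times = [3.0, 5.0, 5.0, 8.0, 11.0]
        events = [1, 1, 1, 0, 1]
        km = km_table(survival_frame(times, events, ["g"] * 5))
        # t=3: 5 at risk, 1 event -> 4/5; t=5: 4 at risk, 2 events -> 4/5 * 2/4
        # t=11: 1 at risk, 1 event -> 0
        np.testing.assert_allclose(
            km["survival"].to_numpy(), [1.0, 0.8, 0.4, 0.0], atol=1e-12
        )
        assert km["n_risk"].tolist() == [5, 5, 4, 1]

    def test_matches_lifelines_oracle(self):
        df = simulated_groups(seed=17, n=150)
        km = km_table(df)
        for group in ("high", "low"):
            sub = df[df["group"] == group]
            kmf = KaplanMeierFitter().fit(sub["time_months"], sub["event"])
            ours = km[km["group"] == group]
            for _, row in ours.iterrows():
                ref = float(kmf.survival_function_at_times(row["time"]).iloc[0])
                assert abs(row["survival"] - ref) < 1e-9

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            km_table(survival_frame([], [], []))


class TestChiSquare:
    def test_paper_sex_table(self):
        """Printed 2x2 sex table: chi2 ~ 9.77, p = 0.0018 at 4 dp."""
        stat, p = chi_square_assoc(np.array([[39, 38], [30, 77]]))
        assert round(p, 4) == 0.0018
        assert abs(stat - 184 * (39 * 77 - 38 * 30) ** 2 / (77 * 107 * 69 * 115)) < 1e-9

    def test_uniform_table_null(self):
        stat, p = chi_square_assoc(np.array([[10, 10], [10, 10]]))
        assert stat == 0.0 and p == 1.0

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    def test_matches_textbook_2x2_formula(self, a, b, c, d):
        """Oracle: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
        stat, _ = chi_square_assoc(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert abs(stat - expected) < 1e-9

    def test_r_by_2_table(self):
        stat, p = chi_square_assoc(np.array([[10, 20], [30, 5], [8, 9]]))
        assert stat > 0 and 0 < p < 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_assoc(np.array([[0, 0], [10, 10]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_assoc(np.array([[-1, 5], [2, 3]]))


def test_label_predicted_groups_joins_patient_level():
    cohort = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b"],
            "slide_id": ["s1", "s2", "s3"],
            "label": [RC, RC, NRC],
            "time_months": [12.0, 12.0, 50.0],
            "event": [1, 1, 0],
        }
    )
    preds = pd.DataFrame(
        {"patient_id": ["a", "a", "b"], "slide_id": ["s1", "s2", "s3"], "p_RC": [0.3, 0.8, 0.1]}
    )
    merged = label_predicted_groups(cohort, preds)
    assert len(merged) == 2
    assert merged.set_index("patient_id").loc["a", "group"] == "high"
    assert merged.set_index("patient_id").loc["b", "group"] == "low"


def test_cox_result_invariant():
    with pytest.raises(ValueError):
        CoxResult(beta=0.0, se=1.0, hr=1.0, ci_low=1.5, ci_high=2.0, p=0.5, n_events=3)
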