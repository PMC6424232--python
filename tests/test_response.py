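import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petflux.errors import DomainError
from petflux.response_pipeline import (
    METRICS,
    classify,
    classify_patients,
    cohort_stats,
    confusion_counts,
    equivalent_sphere_diameter,
    lesion_percent_changes,
    patient_change,
    patient_percent_changes,
    percent_change,
    select_index_lesions,
)


def make_lesions(rows):
    return pd.DataFrame(rows, columns=["lesion_id", "suv_max", "volume_cm3"])


class TestSelectIndexLesions:
    def test_top_five_of_seven(self):
        rows = [(f"L{i}", 10.0 + i, 8.0) for i in range(7)]
        out = select_index_lesions(make_lesions(rows))
        assert len(out) == 5
        assert list(out["lesion_id"]) == ["L6", "L5", "L4", "L3", "L2"]

    def test_suv_threshold(self):
        rows = [("L1", 9.9, 100.0), ("L2", 10.0, 8.0)]
        out = select_index_lesions(make_lesions(rows))
        assert list(out["lesion_id"]) == ["L2"]

    def test_diameter_threshold(self):
        # 1 cm sphere has volume ~0.524 cm^3
        rows = [("L1", 20.0, 0.40), ("L2", 20.0, 0.60)]
        out = select_index_lesions(make_lesions(rows))
        assert list(out["lesion_id"]) == ["L2"]

    def test_fewer_than_cap(self):
        rows = [("L1", 12.0, 5.0), ("L2", 15.0, 5.0), ("L3", 11.0, 5.0)]
        out = select_index_lesions(make_lesions(rows))
        assert len(out) == 3
        assert list(out["lesion_id"]) == ["L2", "L1", "L3"]

    def test_tie_breaking(self):
        rows = [("B", 12.0, 5.0), ("A", 12.0, 5.0), ("C", 12.0, 9.0)]
        out = select_index_lesions(make_lesions(rows))
        assert list(out["lesion_id"]) == ["C", "A", "B"]

    def test_empty_result_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = select_index_lesions(make_lesions([("L1", 2.0, 5.0)]))
        assert out.empty
        assert "no eligible" in caplog.text

    def test_equivalent_sphere_diameter(self):
        assert equivalent_sphere_diameter(np.pi / 6.0) == pytest.approx(1.0)


class TestPercentChange:
    def test_no_change(self):
        assert percent_change(3.0, 3.0) == 0.0

    def test_arithmetic(self):
        assert percent_change(10.0, 15.0) == pytest.approx(50.0)

    def test_boundary_is_sd(self):
        change = percent_change(0.08, 0.06)
        assert change == pytest.approx(-25.0)
        assert classify(change) == "SD"

    def test_error(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 5.0)

    @given(x=st.floats(1e-3, 1e3), p=st.floats(-99.0, 500.0))
    @settings(max_examples=100, deadline=None)
    def test_algebraic_identity(self, x, p):
        assert percent_change(x, x * (1.0 + p / 100.0)) == pytest.approx(p, abs=1e-6)


class TestClassify:
    @pytest.mark.parametrize(
        "change,expected",
        [(97.5, "PD"), (-28.0, "PR"), (20.4, "SD"), (25.0, "SD"), (-25.0, "SD"),
         (25.0001, "PD"), (-25.0001, "PR"), (0.0, "SD")],
    )
    def test_examples(self, change, expected):
        assert classify(change) == expected

    def test_step_monotone(self):
        order = {"PR": 0, "SD": 1, "PD": 2}
        changes = np.linspace(-100, 100, 401)
        ranks = [order[classify(c)] for c in changes]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_non_finite(self):
        with pytest.raises(DomainError):
            classify(float("nan"))

    def test_custom_threshold(self):
        assert classify(30.0, threshold_pct=40.0) == "SD"


class TestPatientChange:
    def test_mean(self):
        assert patient_change([10.0, 20.0, 30.0]) == pytest.approx(20.0)

    def test_single(self):
        assert patient_change([-5.0]) == -5.0

    def test_empty(self):
        with pytest.raises(DomainError):
            patient_change([])

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(11)
        draws = [patient_change(90.0 + rng.normal(0, 10, 5)) for _ in range(200)]
        assert np.mean(draws) == pytest.approx(90.0, abs=2.0)


class TestLesionToPatientTables:
    def test_round_trip(self):
        rows = []
        for visit, scale in (("baseline", 1.0), ("week8", 1.5)):
            for lesion in ("L1", "L2"):
                rows.append(
                    {
                        "patient_id": "P1",
                        "visit": visit,
                        "lesion_id": lesion,
                        "ki": 0.05 * scale,
                        "suv_max": 20.0 * scale,
                        "suv_mean": 10.0 * scale,
                    }
                )
        changes = lesion_percent_changes(pd.DataFrame(rows))
        assert len(changes) == 2
        assert changes["ki_pct_change"].tolist() == pytest.approx([50.0, 50.0])
        per_patient = patient_percent_changes(changes)
        assert per_patient.loc[0, "suv_mean_pct_change"] == pytest.approx(50.0)


class TestFixtureCohort:
    """The packaged 12-patient table reproduces the published cohort numbers."""

    PRINTED = {
        "ki": {"PD": (89.7, 61.7), "non-PD": (11.0, 36.7)},
        "suv_max": {"PD": (41.8, 27.8), "non-PD": (6.2, 28.9)},
        "suv_mean": {"PD": (43.5, 41.9), "non-PD": (7.4, 27.5)},
    }

    def test_group_means_and_sds(self, outcomes, reference_labels):
        summary = cohort_stats(outcomes, reference_labels)
        for metric, groups in self.PRINTED.items():
            for label, (mean, sd) in groups.items():
                got = summary.group_stats[metric][label]
                assert round(got["mean"], 1) == pytest.approx(mean)
                assert got["sd"] == pytest.approx(sd, abs=1.0)

    def test_confusion_counts(self, outcomes, reference_labels):
        classes = classify_patients(outcomes)
        counts = confusion_counts(classes, reference_labels)
        assert counts["ki"]["pd_identified"] == 4
        assert counts["ki"]["non_pd_identified"] == 7
        assert counts["ki"]["false_positives"] == 1
        assert counts["suv_max"]["pd_identified"] == 3
        assert counts["suv_max"]["false_positives"] == 3
        assert counts["suv_mean"]["pd_identified"] == 2
        assert counts["suv_mean"]["false_positives"] == 2

    def test_counts_conserved(self, outcomes, reference_labels):
        classes = classify_patients(outcomes)
        counts = confusion_counts(classes, reference_labels)
        for metric in METRICS:
            c = counts[metric]
            assert c["non_pd_identified"] + c["false_positives"] == c["non_pd_total"]
            assert c["pd_total"] == 4
            assert c["non_pd_total"] == 8

    def test_group_comparison(self, outcomes, reference_labels):
        summary = cohort_stats(outcomes, reference_labels)
        # the net-clearance change separates the groups; SUV changes do not
        assert summary.group_comparison["ki"]["pvalue"] < 0.05
        assert summary.group_comparison["suv_max"]["pvalue"] > 0.05
        assert summary.group_comparison["suv_mean"]["pvalue"] > 0.05


class TestCohortStats:
    def test_pearson_identity(self):
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(6)],
                "ki_pct_change": [1.0, 5.0, -3.0, 8.0, 2.0, -1.0],
            }
        )
        df["suv_max_pct_change"] = df["ki_pct_change"]
        df["suv_mean_pct_change"] = -df["ki_pct_change"]
        reference = {f"P{i}": ("PD" if i < 3 else "non-PD") for i in range(6)}
        summary = cohort_stats(df, reference)
        assert summary.correlations["ki_vs_suv_max"]["pct_change"]["r"] == pytest.approx(1.0)
        assert summary.correlations["ki_vs_suv_mean"]["pct_change"]["r"] == pytest.approx(-1.0)

    def test_paired_tests_present_with_values(self, outcomes, reference_labels):
        long_rows = []
        for visit in ("baseline", "week8"):
            sub = outcomes[["patient_id"]].copy()
            sub["visit"] = visit
            for m in METRICS:
                sub[m] = outcomes[f"{m}_{visit}"]
            long_rows.append(sub)
        values = pd.concat(long_rows, ignore_index=True)
        summary = cohort_stats(outcomes, reference_labels, values_table=values)
        for metric in METRICS:
            assert np.isfinite(summary.paired_tests[metric]["pvalue"])
        for comparison in ("ki_vs_suv_max", "ki_vs_suv_mean"):
            for when in ("baseline", "week8"):
                r = summary.correlations[comparison][when]["r"]
                assert -1.0 <= r <= 1.0

    def test_missing_reference(self, outcomes):
        with pytest.raises(ValueError):
            cohort_stats(outcomes, {"PD-1": "PD"})

    def test_degenerate_variance_warns(self, caplog):
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "ki_pct_change": [1.0] * 4,
                "suv_max_pct_change": [1.0] * 4,
                "suv_mean_pct_change": [1.0] * 4,
            }
        )
        reference = {f"P{i}": ("PD" if i < 2 else "non-PD") for i in range(4)}
        summary = cohort_stats(df, reference)
        assert np.isnan(summary.correlations["ki_vs_suv_max"]["pct_change"]["r"])

    def test_all_zero_changes_no_pd_calls(self):
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "ki_pct_change": [0.0] * 4,
                "suv_max_pct_change": [0.0] * 4,
                "suv_mean_pct_change": [0.0] * 4,
            }
        )
        reference = {f"P{i}": "non-PD" for i in range(4)}
        counts = confusion_counts(classify_patients(df), reference)
        for metric in METRICS:
            assert counts[metric]["false_positives"] == 0
            assert counts[metric]["non_pd_identified"] == 4
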