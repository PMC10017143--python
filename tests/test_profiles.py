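"""Cluster-diagnosis linkage, disease prevalence, demographics, yearly series."""

import numpy as np
import pandas as pd
import pytest

from rxpatterns.assignment import ClusterAssignment
from rxpatterns.profiles import (
    completed_years,
    demographic_composition,
    disease_prevalence,
    link_diagnoses,
    yearly_visit_counts,
)
from rxpatterns.windows import DEFAULT_WINDOWS

DX = pd.Timestamp("2010-01-01")


def _assignment(members_by_factor, cohort_size=10):
    return ClusterAssignment(
        period_index=1, members=members_by_factor, min_drugs=3, cohort_size=cohort_size
    )


def _patients(ids, dx=DX):
    return pd.DataFrame(
        {
            "patient_id": list(ids),
            "gender": ["F"] * len(ids),
            "date_of_birth": [pd.Timestamp("1935-06-15")] * len(ids),
            "diagnosis_date": [dx] * len(ids),
        }
    )


class TestLinkDiagnoses:
    def test_presence_coding_collapses_repeat_events(self):
        dx_events = pd.DataFrame(
            {
                "patient_id": ["A"] * 3,
                "event_date": [DX - pd.Timedelta(days=d) for d in (100, 200, 300)],
                "diagnosis_code": ["H06"] * 3,
            }
        )
        linked = link_diagnoses(
            _assignment({1: {"A"}}), dx_events, _patients(["A"]), DEFAULT_WINDOWS[0]
        )
        assert len(linked) == 1
        assert linked.iloc[0].tolist() == [1, "A", "H06"]

    def test_event_outside_window_excluded(self):
        dx_events = pd.DataFrame(
            {
                "patient_id": ["A"],
                "event_date": [DX - pd.Timedelta(days=int(7 * 365.25))],
                "diagnosis_code": ["H06"],
            }
        )
        linked = link_diagnoses(
            _assignment({1: {"A"}}), dx_events, _patients(["A"]), DEFAULT_WINDOWS[0]
        )
        assert linked.empty

    def test_planted_linkage_recovered(self, small_dataset):
        """The linked table equals the generator's planted member-code pairs."""
        ds = small_dataset
        asg = _assignment(ds.truth.memberships[1], cohort_size=len(ds.truth.presence[1]))
        linked = link_diagnoses(asg, ds.dx_events, ds.patients, DEFAULT_WINDOWS[0])
        # every linked patient is a member, and every (member, code) pair in
        # the linked table has >=1 in-window event
        for f, members in ds.truth.memberships[1].items():
            sub = linked[linked["factor"] == f]
            assert set(sub["patient_id"]) <= members


class TestDiseasePrevalence:
    def test_printed_count_percentage_pairs(self):
        linked = pd.DataFrame(
            {
                "factor": [1] * 4783 + [2] * 1652,
                "patient_id": [f"a{i}" for i in range(4783)] + [f"b{i}" for i in range(1652)],
                "diagnosis_code": ["H06"] * (4783 + 1652),
            }
        )
        out = disease_prevalence(linked, {1: 17947, 2: 5938})
        assert out.loc[out["factor"] == 1, "prevalence_pct"].iloc[0] == 26.65
        assert out.loc[out["factor"] == 2, "prevalence_pct"].iloc[0] == 27.82

    def test_universal_code_is_100_pct(self):
        linked = pd.DataFrame(
            {"factor": [1] * 5, "patient_id": list("abcde"), "diagnosis_code": ["N05"] * 5}
        )
        out = disease_prevalence(linked, {1: 5})
        assert out["prevalence_pct"].iloc[0] == 100.0

    def test_top_k_and_absent_codes(self):
        rows = []
        for j, code in enumerate(["C%02d" % i for i in range(12)]):
            rows += [{"factor": 1, "patient_id": f"p{i}_{j}", "diagnosis_code": code}
                     for i in range(12 - j)]
        linked = pd.DataFrame(rows)
        out = disease_prevalence(linked, {1: 50}, top_k=8)
        assert len(out) == 8
        assert out["n_members_with_code"].tolist() == sorted(
            out["n_members_with_code"], reverse=True
        )

    def test_zero_size_cluster_skipped_with_warning(self):
        linked = pd.DataFrame(columns=["factor", "patient_id", "diagnosis_code"])
        with pytest.warns(UserWarning, match="no members"):
            out = disease_prevalence(linked, {1: 0})
        assert out.empty


class TestDemographics:
    def test_printed_gender_and_age_percentages(self):
        """6335 males of 17947 -> 35.30%; 7778 aged 75-85 of 17947 -> 43.34%."""
        n, n_male, n_7585 = 17947, 6335, 7778
        ids = [f"P{i}" for i in range(n)]
        gender = ["M"] * n_male + ["F"] * (n - n_male)
        age = np.full(n, 70)
        age[:n_7585] = 80  # first block in [75, 86)
        dob = [DX - pd.Timedelta(days=int(a * 365.25) + 10) for a in age]
        patients = pd.DataFrame(
            {"patient_id": ids, "gender": gender, "date_of_birth": dob, "diagnosis_date": DX}
        )
        out = demographic_composition(_assignment({1: set(ids)}, n), patients)
        male = out[(out["stratum_type"] == "gender") & (out["stratum"] == "M")]
        assert male["pct_of_cluster"].iloc[0] == 35.30
        band = out[(out["stratum_type"] == "age_band") & (out["stratum"] == "75-86")]
        assert band["pct_of_cluster"].iloc[0] == 43.34

    def test_single_female_cluster(self):
        patients = _patients(["A"])
        out = demographic_composition(_assignment({1: {"A"}}, 1), patients)
        female = out[(out["stratum_type"] == "gender") & (out["stratum"] == "F")]
        assert female["pct_of_cluster"].iloc[0] == 100.0

    def test_gender_strata_sum_to_cluster(self, small_dataset):
        ds = small_dataset
        asg = _assignment(ds.truth.memberships[1], len(ds.truth.presence[1]))
        out = demographic_composition(asg, ds.patients)
        for f, members in ds.truth.memberships[1].items():
            if not members:
                continue
            g = out[(out["factor"] == f) & (out["stratum_type"] == "gender")]
            assert g["count"].sum() == len(members)
            assert abs(g["pct_of_cluster"].sum() - 100.0) <= 0.02
            a = out[(out["factor"] == f) & (out["stratum_type"] == "age_band")]
            assert a["count"].sum() == len(members)

    def test_missing_demographic_field_named(self):
        patients = _patients(["A", "B"])
        patients.loc[1, "gender"] = None
        with pytest.raises(ValueError, match="B"):
            demographic_composition(_assignment({1: {"A", "B"}}, 2), patients)

    def test_completed_years_boundary(self):
        # birthday not yet reached at reference -> one year less
        assert completed_years(["1940-06-15"], ["2000-06-14"])[0] == 59
        assert completed_years(["1940-06-15"], ["2000-06-15"])[0] == 60


class TestYearlyVisits:
    def test_single_event_offset_and_category(self):
        events = pd.DataFrame(
            {
                "patient_id": ["A"],
                "event_date": [DX - pd.Timedelta(days=int(2.4 * 365.25))],
                "medication_code": ["M001"],
            }
        )
        out = yearly_visit_counts(events, _patients(["A"]), {"M001": "CVD"}, "medication_code")
        cvd = out[out["category"] == "CVD"]
        assert cvd["years_before"].tolist() == [2] and cvd["n_events"].tolist() == [1]

    def test_empty_event_table(self):
        events = pd.DataFrame(columns=["patient_id", "event_date", "medication_code"])
        out = yearly_visit_counts(events, _patients(["A"]), {}, "medication_code")
        assert out.empty

    def test_unmapped_code_bucketed_as_other(self):
        events = pd.DataFrame(
            {"patient_id": ["A"], "event_date": [DX - pd.Timedelta(days=400)],
             "medication_code": ["MYSTERY"]}
        )
        with pytest.warns(UserWarning, match="other"):
            out = yearly_visit_counts(events, _patients(["A"]), {"M001": "CVD"}, "medication_code")
        assert set(out["category"]) == {"other", "total"}

    def test_uniform_dates_spread_and_conservation(self, small_dataset):
        """Counts are conserved (sum over offsets = in-span events) and are
        roughly uniform within a period for uniformly drawn dates."""
        ds = small_dataset
        with pytest.warns(UserWarning, match="other"):
            out = yearly_visit_counts(ds.med_events, ds.patients, {}, "medication_code")
        totals = out[out["category"] == "total"]
        merged = ds.med_events.merge(
            ds.patients[["patient_id", "diagnosis_date"]], on="patient_id"
        )
        delta = (merged["diagnosis_date"] - merged["event_date"]).dt.days / 365.25
        n_in_span = int(((delta >= 0) & (delta < 20)).sum())
        assert totals["n_events"].sum() == n_in_span
        assert set(totals["years_before"]) == set(range(20))
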