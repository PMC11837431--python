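"""Dataset I/O, Cockcroft-Gault, and the cross-protocol inclusion filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabpk import (
    ConcRecord,
    DoseEvent,
    Subject,
    TrialDataset,
    apply_inclusion_filters,
    cockcroft_gault,
    cross_protocol_roster,
    read_dataset,
    write_dataset,
)
from mabpk.errors import IntegrityError, SchemaError, ValidationError


def _one_subject_dataset() -> TrialDataset:
    subj = Subject(id="A1", weight=76.0, age=28.0, sex="male", crcl=131.4,
                   group="single", serum_creatinine=0.9)
    doses = [DoseEvent("A1", 0.0, 380.0, "IV")]
    times = [1.0, 3.0, 6.0, 14.0, 28.0, 56.0, 84.0]
    obs = [ConcRecord("A1", t, 100.0 * np.exp(-0.015 * t)) for t in times]
    return TrialDataset([subj], doses, obs)


class TestDatasetRoundTrip:
    def test_row_counts(self, tmp_path):
        ds = _one_subject_dataset()
        write_dataset(ds, tmp_path / "pk.csv", tmp_path / "cov.csv")
        back = read_dataset(tmp_path / "pk.csv", tmp_path / "cov.csv")
        assert len(back.subjects) == 1
        assert len(back.doses) == 1
        assert len(back.observations) == 7

    def test_values_preserved(self, tmp_path):
        ds = _one_subject_dataset()
        write_dataset(ds, tmp_path / "pk.csv", tmp_path / "cov.csv")
        back = read_dataset(tmp_path / "pk.csv", tmp_path / "cov.csv")
        for a, b in zip(ds.observations, back.observations):
            assert b.conc == pytest.approx(a.conc, rel=1e-6)
            assert b.time == a.time and b.blq == a.blq
        assert back.subjects[0].weight == ds.subjects[0].weight
        assert back.doses[0].amount == ds.doses[0].amount

    def test_dangling_subject_is_integrity_error(self):
        ds = _one_subject_dataset()
        with pytest.raises(IntegrityError, match="X9"):
            TrialDataset(ds.subjects, ds.doses,
                         ds.observations + [ConcRecord("X9", 1.0, 5.0)])

    def test_missing_column_names_the_column(self, tmp_path):
        ds = _one_subject_dataset()
        write_dataset(ds, tmp_path / "pk.csv", tmp_path / "cov.csv")
        pk = pd.read_csv(tmp_path / "pk.csv").drop(columns=["EVID"])
        pk.to_csv(tmp_path / "pk_bad.csv", index=False)
        with pytest.raises(SchemaError, match="EVID"):
            read_dataset(tmp_path / "pk_bad.csv", tmp_path / "cov.csv")

    def test_time_unit_conversion(self, tmp_path):
        ds = _one_subject_dataset()
        write_dataset(ds, tmp_path / "pk.csv", tmp_path / "cov.csv")
        pk = pd.read_csv(tmp_path / "pk.csv")
        pk["TIME"] = pk["TIME"] * 24.0
        pk["TIME_UNIT"] = "hours"
        pk.to_csv(tmp_path / "pk_h.csv", index=False)
        back = read_dataset(tmp_path / "pk_h.csv", tmp_path / "cov.csv")
        assert [o.time for o in back.observations] == [o.time for o in ds.observations]

    def test_blq_records_kept_not_dropped(self, tmp_path):
        ds = _one_subject_dataset()
        ds.observations.append(ConcRecord("A1", 120.0, 0.0, blq=True, lloq=1.0))
        write_dataset(ds, tmp_path / "pk.csv", tmp_path / "cov.csv")
        back = read_dataset(tmp_path / "pk.csv", tmp_path / "cov.csv")
        assert sum(o.blq for o in back.observations) == 1

    def test_dose_times_must_increase(self):
        subj = _one_subject_dataset().subjects
        doses = [DoseEvent("A1", 0.0, 380.0, "IV"), DoseEvent("A1", 0.0, 380.0, "IV")]
        with pytest.raises(IntegrityError):
            TrialDataset(subj, doses, [])


class TestCockcroftGault:
    def test_worked_examples(self):
        assert cockcroft_gault(76, 28, 0.9, "male") == pytest.approx(131.4, abs=0.05)
        assert cockcroft_gault(76, 28, 0.9, "female") == pytest.approx(111.7, abs=0.05)

    def test_linearity_in_weight(self):
        assert cockcroft_gault(152, 28, 0.9, "male") == pytest.approx(
            2 * cockcroft_gault(76, 28, 0.9, "male"))

    @given(w=st.floats(40, 150), a=st.floats(18, 80), s=st.floats(0.5, 2.0))
    @settings(max_examples=40, deadline=None)
    def test_monotonicity(self, w, a, s):
        base = cockcroft_gault(w, a, s, "male")
        assert cockcroft_gault(w * 1.1, a, s, "male") > base
        assert cockcroft_gault(w, a + 5, s, "male") < base
        assert cockcroft_gault(w, a, s * 1.1, "male") < base

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cockcroft_gault(76, 140, 0.9, "male")
        with pytest.raises(ValueError):
            cockcroft_gault(-5, 28, 0.9, "male")


class TestInclusionFilters:
    def test_cross_protocol_counts(self):
        retained, tally = apply_inclusion_filters(cross_protocol_roster())
        assert tally["total"] == 124 + 27 + 32
        assert tally["retained"] == 146
        counts = retained.groupby("GROUP").size()
        assert counts["single"] == 100 and counts["combination"] == 46
        assert tally["excluded_im_route"] == 21
        assert tally["excluded_placebo"] == 3
        assert tally["excluded_not_received"] == 13

    def test_tally_partitions_roster(self):
        _, tally = apply_inclusion_filters(cross_protocol_roster())
        assert (tally["retained"] + tally["excluded_im_route"]
                + tally["excluded_placebo"] + tally["excluded_not_received"]
                == tally["total"])

    def test_no_exclusion_flags_retains_all(self):
        roster = pd.DataFrame(dict(ID=["a", "b"], ROUTE=["IV", "SC"],
                                   ARM=["active", "active"], RECEIVED=[True, True]))
        retained, tally = apply_inclusion_filters(roster)
        assert len(retained) == 2 and tally["retained"] == 2

    def test_all_placebo_empty(self):
        roster = pd.DataFrame(dict(ID=["a", "b"], ROUTE=["IV", "SC"],
                                   ARM=["placebo", "placebo"], RECEIVED=[True, True]))
        retained, tally = apply_inclusion_filters(roster)
        assert retained.empty and tally["excluded_placebo"] == tally["total"]

    def test_unknown_route_is_validation_error(self):
        roster = pd.DataFrame(dict(ID=["a"], ROUTE=["oral"], ARM=["active"],
                                   RECEIVED=[True]))
        with pytest.raises(ValidationError, match="route"):
            apply_inclusion_filters(roster)


class TestDomainValidation:
    def test_subject_invariants(self):
        with pytest.raises(ValidationError):
            Subject("x", weight=-1, age=30, sex="male", crcl=100, group="single")
        with pytest.raises(ValidationError):
            Subject("x", weight=70, age=30, sex="other", crcl=100, group="single")

    def test_dose_and_record_invariants(self):
        with pytest.raises(ValidationError):
            DoseEvent("x", 0.0, -5.0, "IV")
        with pytest.raises(ValidationError):
            DoseEvent("x", 0.0, 5.0, "IM")
        with pytest.raises(ValidationError):
            ConcRecord("x", 1.0, -2.0)
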