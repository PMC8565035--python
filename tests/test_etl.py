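"""Sample selection, routing, linking, and worked mapping examples."""

import copy
import datetime as dt

import pytest

from omopmap.config import MappingConfig
from omopmap.dates import PartialDate
from omopmap.etl import (
    CdmOutput,
    attach_characteristic,
    derive_observation_period,
    emit_combination,
    filter_non_events,
    map_disposition,
    map_outcome,
    route_record,
    run_mapping,
    select_sample,
)
from omopmap.fixtures import TABLE_CONCEPT_IDS
from omopmap.sdtm import DomainTable, SDTMRecord, StudyDataset, read_study, write_study
from omopmap.vocabulary import combine_concepts


def dm_record(pid, seq=1, birth="1960", spid=None, **extra):
    values = {"USUBJID": pid, "DMSPID": spid or f"K{pid}", "BRTHDTC": birth,
              "SEX": "F", "RFSTDTC": "2015-01-10"}
    values.update(extra)
    return SDTMRecord(pid, "DM", seq, values)


def make_study(dm_records, violators=(), ex_records=None):
    study = StudyDataset("T", tables={"DM": DomainTable("DM", dm_records)},
                         violator_ids=set(violators))
    if ex_records is not None:
        study.tables["EX"] = DomainTable("EX", ex_records)
    return study


class TestSampleSelection:
    def test_missing_birth_year_excluded(self):
        study = make_study([dm_record("P1", birth=""), dm_record("P2")])
        retained, report, log = select_sample(study)
        assert retained == ["P2"]
        assert ("P1", "missing_birth_year") in log
        assert report.n_mapping_excluded == 1

    def test_violators_excluded_in_their_own_category(self):
        study = make_study([dm_record("P1"), dm_record("P2")], violators={"P1"})
        retained, report, log = select_sample(study)
        assert retained == ["P2"]
        assert report.n_violators == 1 and report.n_mapping_excluded == 0

    def test_identical_dm_rows_for_one_patient_keep_first(self):
        rec = dm_record("P1")
        twin = SDTMRecord("P1", "DM", 2, dict(rec.values))
        study = make_study([rec, twin, dm_record("P2")])
        retained, report, log = select_sample(study)
        assert retained == ["P1", "P2"]
        assert ("P1", "duplicate_row") in log
        assert report.n_in_database == 2

    def test_clone_patient_sharing_person_key_excluded(self):
        study = make_study(
            [dm_record("P1", spid="SP1"), dm_record("P1D", spid="SP1")]
        )
        retained, report, log = select_sample(study)
        assert retained == ["P1"]
        assert ("P1D", "duplicate") in log

    def test_missing_both_treatment_dates_excluded(self):
        ex = [
            SDTMRecord("P1", "EX", 1, {"EXSTDTC": "", "EXENDTC": ""}),
            SDTMRecord("P2", "EX", 1, {"EXSTDTC": "2015-02", "EXENDTC": ""},
                       start_date=PartialDate(2015, 2)),
        ]
        study = make_study([dm_record("P1"), dm_record("P2")], ex_records=ex)
        retained, report, _ = select_sample(study)
        assert retained == ["P2"]

    def test_fully_populated_non_violator_retained(self):
        study = make_study([dm_record("P1")])
        retained, report, log = select_sample(study)
        assert retained == ["P1"] and report.n_mapped == 1 and not log

    def test_accounting_identity_holds(self, small_study, store):
        _, study, _ = small_study
        _, report, _ = select_sample(study)
        assert report.n_mapped == (
            report.n_in_database - report.n_violators - report.n_mapping_excluded
        )


class TestNonEventFilter:
    @pytest.mark.parametrize(
        "occur, stat, expect_reason",
        [
            ("N", None, "not_occurred"),
            ("U", None, "unknown"),
            (None, "NOT DONE", "not_done"),
            ("Y", None, None),
            (None, None, None),
        ],
    )
    def test_flag_semantics(self, occur, stat, expect_reason):
        rec = SDTMRecord("P1", "AE", 1, {}, occur_flag=occur, status_flag=stat)
        kept, dropped = filter_non_events(DomainTable("AE", [rec]))
        if expect_reason is None:
            assert kept == [rec] and not dropped
        else:
            assert not kept and dropped[0][1] == expect_reason


class TestWorkedExamples:
    """The two published worked mappings, reproduced end to end."""

    def test_moderate_renal_impairment_pattern(self, store):
        output = CdmOutput()
        condition = output.new_event(
            "condition_occurrence", person_id=1, concept_id=4030518,
            start_date=dt.date(2015, 6, 1),
        )
        rel = store.register_custom_concept("Has characteristic", "Metadata", [])
        obs, (fwd, inv) = attach_characteristic(condition, 4022772, 4285732,
                                                output, rel)
        assert obs.concept_id == 4022772
        assert obs.value_as_concept_id == 4285732
        assert fwd.fact_id_1 == condition.event_id
        assert fwd.fact_id_2 == obs.event_id
        # mirrored inverse row present with facts swapped
        assert (inv.fact_id_1, inv.fact_id_2) == (obs.event_id, condition.event_id)

    def test_mpap_thermodilution_pattern(self, store):
        output = CdmOutput()
        mpap = output.new_event(
            "measurement", person_id=1, concept_id=3028074,
            start_date=dt.date(2015, 6, 1), value_as_number=48.0,
        )
        obs, pair = attach_characteristic(mpap, 4122989, None, output, 4152892)
        assert obs.concept_id == 4122989
        assert all(f.relationship_concept_id == 4152892 for f in pair)
        orientations = {
            (f.domain_concept_id_1, f.domain_concept_id_2) for f in pair
        }
        # the published orientation (observation -> measurement) and its mirror
        assert orientations == {(1147304, 1147330), (1147330, 1147304)}
        printed = next(f for f in pair if f.domain_concept_id_1 == 1147304)
        assert printed.fact_id_1 == obs.event_id
        assert printed.fact_id_2 == mpap.event_id

    def test_meddra_fan_out_to_two_conditions(self, store):
        rec = SDTMRecord("P1", "AE", 1, {"AEPTCD": "10057688"},
                         coded_term=("MedDRA", "10057688"))
        targets, _ = store.resolve_source("MedDRA", "10057688")
        output = CdmOutput()
        rows = route_record(rec, targets, store, 1, dt.date(2015, 6, 1), None, output)
        assert [r.concept_id for r in rows] == [4249456, 4183956]
        assert all(r.table == "condition_occurrence" for r in rows)
        assert len({r.source_concept_id for r in rows}) == 1
        assert rows[0].source_concept_id is not None  # the MedDRA concept

    def test_unresolved_record_emits_nothing(self, store):
        rec = SDTMRecord("P1", "CM", 1, {}, free_text="zzz-nonsense")
        output = CdmOutput()
        rows = route_record(rec, [], store, 1, dt.date(2015, 6, 1), None, output)
        assert rows == [] and not output.all_events()

    def test_combination_recipe_emits_linked_rows(self, store):
        combo = combine_concepts(37000001, [37000003], store)
        output = CdmOutput()
        rel = store.register_custom_concept("Has characteristic", "Metadata", [])
        rows = emit_combination(combo, store, 1, dt.date(2015, 1, 1), output, rel)
        assert len(rows) == 2
        assert len(output.fact_relationships) == 2  # one mirrored pair


class TestDisposition:
    def make_ds(self, decod, reason=""):
        return SDTMRecord("P1", "DS", 1, {"DSDECOD": decod, "DSREAS": reason})

    def test_enrollment_carries_study_name(self, store):
        output = CdmOutput()
        config = MappingConfig(study_id="REG-A")
        obs = map_disposition(self.make_ds("ENROLLMENT"), 1,
                              dt.date(2015, 1, 10), config, store, output)
        assert obs.concept_id == 44807982
        assert obs.value_as_string == "REG-A"

    def test_consent_and_withdrawal_concepts(self, store):
        output = CdmOutput()
        config = MappingConfig()
        consent = map_disposition(self.make_ds("CONSENT"), 1,
                                  dt.date(2015, 1, 3), config, store, output)
        withdrawal = map_disposition(self.make_ds("WITHDRAWAL", "OTHER"), 1,
                                     dt.date(2016, 1, 3), config, store, output)
        assert consent.concept_id == 44811375
        assert withdrawal.concept_id == 44810920
        assert withdrawal.value_as_concept_id == 45885208  # Other reason

    def test_configured_alternatives_are_honoured(self, store):
        output = CdmOutput()
        config = MappingConfig(
            disposition_concepts={"enrollment": 4090379, "consent": 4163733,
                                  "completion": 40482840, "withdrawal": 4087907}
        )
        obs = map_disposition(self.make_ds("ENROLLMENT"), 1,
                              dt.date(2015, 1, 10), config, store, output)
        assert obs.concept_id == 4090379

    def test_unknown_category_maps_nothing(self, store):
        output = CdmOutput()
        assert map_disposition(self.make_ds("SOMETHING ELSE"), 1,
                               dt.date(2015, 1, 10), MappingConfig(), store,
                               output) is None


def test_outcome_observation_links_back(store):
    output = CdmOutput()
    event = output.new_event("condition_occurrence", person_id=1,
                             concept_id=4030518, start_date=dt.date(2015, 6, 1))
    rel = store.register_custom_concept("Has characteristic", "Metadata", [])
    obs, (fwd, _) = map_outcome(event, 4165327, output, rel)
    assert obs.concept_id == 4231813
    assert obs.value_as_concept_id == 4165327
    assert fwd.fact_id_1 == event.event_id


class TestObservationPeriod:
    def make_event(self, output, day, end=None):
        return output.new_event("condition_occurrence", person_id=1,
                               concept_id=4030518,
                               start_date=dt.date(2015, 1, day),
                               end_date=end)

    def test_spans_min_to_max(self):
        output = CdmOutput()
        events = [self.make_event(output, 10), self.make_event(output, 3),
                  self.make_event(output, 20)]
        _, start, end = derive_observation_period(1, events, None)
        assert (start, end) == (dt.date(2015, 1, 3), dt.date(2015, 1, 20))

    def test_death_after_last_event_extends_period(self):
        output = CdmOutput()
        events = [self.make_event(output, 10)]
        _, _, end = derive_observation_period(1, events, dt.date(2016, 3, 20))
        assert end == dt.date(2016, 3, 20)

    def test_single_event_gives_zero_length_period(self):
        output = CdmOutput()
        events = [self.make_event(output, 10)]
        _, start, end = derive_observation_period(1, events, None)
        assert start == end


class TestFullRun:
    def test_no_classification_concept_as_event_concept(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        for event in output.all_events():
            concept = store.concepts[event.concept_id]
            assert concept.standard_flag != "classification"

    def test_fact_relationships_come_in_mirrored_pairs(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        assert output.fact_relationships, "expected linked facts"
        rows = set(output.fact_relationships)
        for f in output.fact_relationships:
            assert (
                f.domain_concept_id_2, f.fact_id_2, f.domain_concept_id_1,
                f.fact_id_1,
            ) in {(r.domain_concept_id_1, r.fact_id_1, r.domain_concept_id_2,
                   r.fact_id_2) for r in rows if
                  r.relationship_concept_id == f.relationship_concept_id}

    def test_every_imputed_date_has_an_audit_entry(self, small_study, store):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        audited = {(r[0], r[1], int(r[2])) for r in output.imputation_audit}
        # every event whose source record had a partial start appears
        partial_keys = set()
        for domain, table in study.tables.items():
            for rec in table:
                if rec.start_date is not None and not rec.start_date.is_complete:
                    partial_keys.add(rec.key)
        emitted_keys = {
            e.source_key for e in output.all_events() if e.source_key
        }
        for key in partial_keys & emitted_keys:
            assert key in audited

    def test_byte_identical_reruns(self, small_study, store, tmp_path):
        config, study, _ = small_study
        a, b = tmp_path / "a", tmp_path / "b"
        run_mapping(study, copy.deepcopy(store), config.mapping_config()).write(a)
        run_mapping(study, copy.deepcopy(store), config.mapping_config()).write(b)
        for path in sorted(a.iterdir()):
            assert path.read_bytes() == (b / path.name).read_bytes()

    def test_observation_periods_contain_all_person_events(
        self, small_study, store
    ):
        config, study, _ = small_study
        output = run_mapping(study, copy.deepcopy(store), config.mapping_config())
        periods = {pid: (s, e) for _, pid, s, e in output.observation_periods}
        for event in output.all_events():
            start, end = periods[event.person_id]
            assert start <= event.start_date <= end
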