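"""Sample selection, non-occurrence filtering, domain routing, linking.

The conversion runs in fixed stages so that identical inputs always give
byte-identical outputs:

1. **sample selection** — protocol violators, patients with essential data
   completely missing (birth year; treatment start and end dates), and
   duplicate patient records are excluded, with a two-row accounting
   (violators vs. mapping exclusions) and a per-patient exclusion log;
2. **non-event filtering** — records stating that an event did not occur,
   is unknown, or was not done are not mapped (CDM convention) and are
   counted per reason;
3. **date completion** — every surviving record gets a complete date via
   the imputation strategies, each completion audited;
4. **routing** — each record's source code or text resolves to standard
   (or custom) concepts; one event row is emitted per resolved concept
   (one-to-many fan-out), into the CDM table its domain dictates;
   unresolved records go to the unmapped log, never silently away;
5. **linking** — characteristics (severity, causality, method of
   measurement), outcomes and combination recipes become observation rows
   tied to their event through mirrored FACT_RELATIONSHIP pairs.

Every input record of a retained patient ends up in exactly one place:
a CDM table, the non-event log, the unmapped log, or the undatable log.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .config import MappingConfig
from .dates import PartialDate, extract_date_from_text
from .fixtures import (
    CAUSALITY_VALUE_IDS,
    CONDITION_SEVERITY_ID,
    GENDER_CONCEPT_IDS,
    MEASUREMENT_METHOD_REL_ID,
    OUTCOME_CATEGORY_ID,
    OUTCOME_VALUE_IDS,
    SEVERITY_VALUE_IDS,
    TABLE_CONCEPT_IDS,
    THERMODILUTION_ID,
)
from .imputation import (
    DeathCandidate,
    ImputationResult,
    ReferenceTimeline,
    UnresolvableDateError,
    impute_by_timepoint,
    impute_death_date,
    impute_drug_start,
    impute_generic,
    impute_lab_date,
)
from .sdtm import DomainTable, SDTMRecord, StudyDataset
from .vocabulary import DOMAIN_TO_TABLE, ConceptCombination, VocabularyStore

__all__ = [
    "PersonRecord",
    "EventRecord",
    "DeathRecord",
    "FactRelationship",
    "ExclusionReport",
    "CdmOutput",
    "select_sample",
    "filter_non_events",
    "route_record",
    "attach_characteristic",
    "map_disposition",
    "map_outcome",
    "emit_combination",
    "derive_observation_period",
    "run_mapping",
]

EVENT_DOMAINS = ("AE", "CM", "EX", "LB", "MH", "VS", "XP")
EVENT_TABLES = (
    "condition_occurrence",
    "drug_exposure",
    "measurement",
    "observation",
    "procedure_occurrence",
    "visit_occurrence",
)


@dataclass
class PersonRecord:
    person_id: int
    source_patient_id: str
    year_of_birth: int
    gender_concept_id: int
    gender_source_value: str


@dataclass
class EventRecord:
    event_id: int
    person_id: int
    table: str
    concept_id: int
    start_date: dt.date
    end_date: Optional[dt.date] = None
    value_as_concept_id: Optional[int] = None
    value_as_number: Optional[float] = None
    value_as_string: Optional[str] = None
    unit_concept_id: Optional[int] = None
    source_value: str = ""
    source_concept_id: Optional[int] = None
    #: provenance key of the source row (patient, domain, seq)
    source_key: Optional[Tuple[str, str, int]] = None
    #: True for rows derived from another event (linked characteristics,
    #: outcomes, methods) rather than from the source record's own term
    derived: bool = False

    def __post_init__(self) -> None:
        if self.table not in EVENT_TABLES:
            raise ValueError(f"unknown CDM event table {self.table!r}")


@dataclass
class DeathRecord:
    person_id: int
    death_date: dt.date
    cause_concept_id: Optional[int] = None
    cause_source_value: Optional[str] = None


@dataclass(frozen=True)
class FactRelationship:
    domain_concept_id_1: int
    fact_id_1: int
    domain_concept_id_2: int
    fact_id_2: int
    relationship_concept_id: int


@dataclass
class ExclusionReport:
    """The two-exclusion-row patient accounting of a conversion."""

    n_in_database: int
    n_violators: int
    n_mapping_excluded: int

    @property
    def n_mapped(self) -> int:
        return self.n_in_database - self.n_violators - self.n_mapping_excluded

    def _pct(self, n: int) -> float:
        from .qa import round_half_up

        return round_half_up(100.0 * n / self.n_in_database, 1)

    @property
    def pct_violators(self) -> float:
        return self._pct(self.n_violators)

    @property
    def pct_mapping_excluded(self) -> float:
        return self._pct(self.n_mapping_excluded)

    @property
    def pct_mapped(self) -> float:
        return self._pct(self.n_mapped)


@dataclass
class CdmOutput:
    """All CDM tables, logs and reports produced by one conversion run."""

    persons: List[PersonRecord] = field(default_factory=list)
    observation_periods: List[Tuple[int, int, dt.date, dt.date]] = field(default_factory=list)
    events: Dict[str, List[EventRecord]] = field(
        default_factory=lambda: {t: [] for t in EVENT_TABLES}
    )
    deaths: List[DeathRecord] = field(default_factory=list)
    fact_relationships: List[FactRelationship] = field(default_factory=list)
    exclusion_report: Optional[ExclusionReport] = None
    exclusion_log: List[Tuple[str, str]] = field(default_factory=list)
    non_event_log: List[Tuple[str, str, int, str]] = field(default_factory=list)
    unmapped_log: List[Tuple[str, str, int, str, str]] = field(default_factory=list)
    undatable_log: List[Tuple[str, str, int, str]] = field(default_factory=list)
    imputation_audit: List[Tuple[str, str, int, str, str, str, str]] = field(default_factory=list)

    def new_event(self, table: str, **kwargs) -> EventRecord:
        rec = EventRecord(event_id=len(self.events[table]) + 1, table=table, **kwargs)
        self.events[table].append(rec)
        return rec

    def link(
        self,
        event_1: EventRecord,
        event_2: EventRecord,
        relationship_concept_id: int,
    ) -> Tuple[FactRelationship, FactRelationship]:
        """Emit the mirrored FACT_RELATIONSHIP pair linking two facts."""
        d1 = TABLE_CONCEPT_IDS[event_1.table]
        d2 = TABLE_CONCEPT_IDS[event_2.table]
        forward = FactRelationship(
            d1, event_1.event_id, d2, event_2.event_id, relationship_concept_id
        )
        inverse = FactRelationship(
            d2, event_2.event_id, d1, event_1.event_id, relationship_concept_id
        )
        self.fact_relationships.extend((forward, inverse))
        return forward, inverse

    def all_events(self) -> List[EventRecord]:
        return [e for t in EVENT_TABLES for e in self.events[t]]

    def record_audit(self, key: Tuple[str, str, int], result: ImputationResult) -> None:
        if result.was_imputed:
            from .imputation import audit_row

            self.imputation_audit.append(audit_row(*key, result))

    # -- serialization ----------------------------------------------------

    def write(self, dir_path: Path | str) -> None:
        dir_path = Path(dir_path)
        dir_path.mkdir(parents=True, exist_ok=True)
        _w = _write_csv
        _w(dir_path / "PERSON.csv",
           ["person_id", "gender_concept_id", "year_of_birth",
            "gender_source_value", "person_source_value"],
           [[p.person_id, p.gender_concept_id, p.year_of_birth,
             p.gender_source_value, p.source_patient_id] for p in self.persons])
        _w(dir_path / "OBSERVATION_PERIOD.csv",
           ["observation_period_id", "person_id",
            "observation_period_start_date", "observation_period_end_date",
            "period_type_concept_id"],
           [[i, pid, s.isoformat(), e.isoformat(), 0]
            for i, pid, s, e in self.observation_periods])
        prefixes = {
            "condition_occurrence": "condition",
            "drug_exposure": "drug",
            "measurement": "measurement",
            "observation": "observation",
            "procedure_occurrence": "procedure",
            "visit_occurrence": "visit",
        }
        for table in EVENT_TABLES:
            p = prefixes[table]
            _w(dir_path / f"{table.upper()}.csv",
               [f"{table}_id", "person_id", f"{p}_concept_id",
                f"{p}_start_date", f"{p}_end_date", "value_as_concept_id",
                "value_as_number", "value_as_string", "unit_concept_id",
                f"{p}_source_value", f"{p}_source_concept_id",
                f"{p}_type_concept_id"],
               [[e.event_id, e.person_id, e.concept_id,
                 e.start_date.isoformat(),
                 e.end_date.isoformat() if e.end_date else "",
                 e.value_as_concept_id if e.value_as_concept_id is not None else "",
                 e.value_as_number if e.value_as_number is not None else "",
                 e.value_as_string or "",
                 e.unit_concept_id if e.unit_concept_id is not None else "",
                 e.source_value,
                 e.source_concept_id if e.source_concept_id is not None else "",
                 0]
                for e in self.events[table]])
        _w(dir_path / "DEATH.csv",
           ["person_id", "death_date", "death_type_concept_id",
            "cause_concept_id", "cause_source_value"],
           [[d.person_id, d.death_date.isoformat(), 0,
             d.cause_concept_id if d.cause_concept_id is not None else "",
             d.cause_source_value or ""] for d in self.deaths])
        _w(dir_path / "FACT_RELATIONSHIP.csv",
           ["domain_concept_id_1", "fact_id_1", "domain_concept_id_2",
            "fact_id_2", "relationship_concept_id"],
           [[f.domain_concept_id_1, f.fact_id_1, f.domain_concept_id_2,
             f.fact_id_2, f.relationship_concept_id]
            for f in self.fact_relationships])
        _w(dir_path / "provenance.csv",
           ["table", "event_id", "patient_id", "domain", "seq", "derived"],
           [[t, e.event_id,
             e.source_key[0] if e.source_key else "",
             e.source_key[1] if e.source_key else "",
             e.source_key[2] if e.source_key else "",
             int(e.derived)]
            for t in EVENT_TABLES for e in self.events[t]])
        _w(dir_path / "exclusion_log.csv", ["patient_id", "reason"],
           [list(r) for r in self.exclusion_log])
        _w(dir_path / "non_event_log.csv",
           ["patient_id", "domain", "seq", "reason"],
           [list(r) for r in self.non_event_log])
        _w(dir_path / "unmapped_log.csv",
           ["patient_id", "domain", "seq", "vocabulary", "source_value"],
           [list(r) for r in self.unmapped_log])
        _w(dir_path / "undatable_log.csv",
           ["patient_id", "domain", "seq", "reason"],
           [list(r) for r in self.undatable_log])
        _w(dir_path / "imputation_audit.csv",
           ["patient_id", "domain", "seq", "original", "imputed",
            "strategy", "notes"],
           [list(r) for r in self.imputation_audit])
        if self.exclusion_report is not None:
            r = self.exclusion_report
            _w(dir_path / "exclusion_report.csv",
               ["n_in_database", "n_violators", "pct_violators",
                "n_mapping_excluded", "pct_mapping_excluded",
                "n_mapped", "pct_mapped"],
               [[r.n_in_database, r.n_violators, r.pct_violators,
                 r.n_mapping_excluded, r.pct_mapping_excluded,
                 r.n_mapped, r.pct_mapped]])


def _write_csv(path: Path, header: List[str], rows: List[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# stage 1: sample selection
# ---------------------------------------------------------------------------

PERSON_KEY_VAR = "DMSPID"  # sponsor-defined person key, used for duplicates


def select_sample(
    study: StudyDataset,
) -> Tuple[List[str], ExclusionReport, List[Tuple[str, str]]]:
    """Select the mappable patients and account for every exclusion.

    Exclusion categories, in precedence order per patient: flagged protocol
    violator; duplicate patient record (a later patient sharing the sponsor
    person key of an earlier one — only the first is kept); birth year
    completely missing; treatment start *and* end dates completely missing.
    Literal duplicate DM rows for one patient are collapsed to the first
    with a row-level log entry.  The report's two exclusion rows are
    violators vs. everything excluded by mapping conventions.
    """
    dm = study.tables.get("DM")
    if dm is None:
        raise ValueError("study has no DM table")

    log: List[Tuple[str, str]] = []
    first_rows: Dict[str, SDTMRecord] = {}
    for rec in dm:
        prev = first_rows.get(rec.patient_id)
        if prev is not None:
            if rec.values == prev.values:
                log.append((rec.patient_id, "duplicate_row"))
            continue
        first_rows[rec.patient_id] = rec

    ex_dates: Dict[str, bool] = {}
    ex_table = study.tables.get("EX")
    if ex_table is not None:
        for rec in ex_table:
            if rec.start_date is not None or rec.end_date is not None:
                ex_dates[rec.patient_id] = True

    retained: List[str] = []
    seen_person_keys: Dict[str, str] = {}
    n_violators = 0
    n_mapping_excluded = 0
    for pid, rec in first_rows.items():
        person_key = (rec.values.get(PERSON_KEY_VAR) or "").strip()
        is_duplicate = bool(person_key) and person_key in seen_person_keys
        if person_key:
            # a violator still occupies its person key, so a later clone of
            # a violator is excluded as a duplicate, not double-counted
            seen_person_keys.setdefault(person_key, pid)
        if pid in study.violator_ids:
            n_violators += 1
            log.append((pid, "protocol_violator"))
            continue
        if is_duplicate:
            n_mapping_excluded += 1
            log.append((pid, "duplicate"))
            continue
        if _birth_year(rec) is None:
            n_mapping_excluded += 1
            log.append((pid, "missing_birth_year"))
            continue
        if ex_table is not None and not ex_dates.get(pid, False):
            n_mapping_excluded += 1
            log.append((pid, "missing_treatment_dates"))
            continue
        retained.append(pid)

    report = ExclusionReport(len(first_rows), n_violators, n_mapping_excluded)
    return retained, report, log


def _birth_year(dm_rec: SDTMRecord) -> Optional[int]:
    text = (dm_rec.values.get("BRTHDTC") or "").strip()
    if len(text) >= 4 and text[:4].isdigit():
        return int(text[:4])
    return None


# ---------------------------------------------------------------------------
# stage 2: non-event filtering
# ---------------------------------------------------------------------------

def filter_non_events(
    table: DomainTable,
) -> Tuple[List[SDTMRecord], List[Tuple[SDTMRecord, str]]]:
    """Split a table into mappable records and non-events with reasons.

    Records whose occurrence flag is N ('not occurred') or U ('unknown'),
    or whose status is NOT DONE, are not mapped, per the CDM convention of
    only recording events that actually happened.
    """
    kept: List[SDTMRecord] = []
    dropped: List[Tuple[SDTMRecord, str]] = []
    for rec in table:
        if rec.occur_flag == "N":
            dropped.append((rec, "not_occurred"))
        elif rec.occur_flag == "U":
            dropped.append((rec, "unknown"))
        elif rec.status_flag == "NOT DONE":
            dropped.append((rec, "not_done"))
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# stage 4/5: routing and linking
# ---------------------------------------------------------------------------

def route_record(
    rec: SDTMRecord,
    resolution: Sequence[int],
    store: VocabularyStore,
    person_id: int,
    start_date: dt.date,
    end_date: Optional[dt.date],
    output: CdmOutput,
) -> List[EventRecord]:
    """Emit one event row per resolved concept into its domain's table.

    The target table is dictated by each concept's domain.  Classification
    concepts never become an event's concept_id — the matching source
    (e.g. MedDRA) concept id rides along in ``source_concept_id`` instead.
    An empty resolution emits nothing; the caller logs it as unmapped.
    """
    source_value = rec.coded_term[1] if rec.coded_term else (rec.free_text or "")
    source_concept_id = None
    if rec.coded_term is not None:
        src = store._concept_by_code(*rec.coded_term)
        if src is not None and src.standard_flag != "standard":
            source_concept_id = src.concept_id

    emitted: List[EventRecord] = []
    for cid in resolution:
        concept = store.concepts[cid]
        table = DOMAIN_TO_TABLE.get(concept.domain_id)
        if table is None:
            raise ValueError(
                f"concept {cid} has unroutable domain {concept.domain_id!r} "
                "(vocabulary fixture bug)"
            )
        emitted.append(
            output.new_event(
                table,
                person_id=person_id,
                concept_id=cid,
                start_date=start_date,
                end_date=end_date,
                source_value=source_value,
                source_concept_id=source_concept_id,
                source_key=rec.key,
            )
        )
    return emitted


HAS_CHARACTERISTIC_NAME = "Has characteristic"


def attach_characteristic(
    event: EventRecord,
    characteristic_concept_id: int,
    value_concept_id: Optional[int],
    output: CdmOutput,
    relationship_concept_id: int,
) -> Tuple[EventRecord, Tuple[FactRelationship, FactRelationship]]:
    """Record a characteristic of an event as a linked observation.

    The characteristic (severity, causality, method of measurement, ...)
    becomes an observation row — characteristic as its concept, assessment
    as value_as_concept_id, same person and date — tied to the event by a
    mirrored FACT_RELATIONSHIP pair.
    """
    obs = output.new_event(
        "observation",
        person_id=event.person_id,
        concept_id=characteristic_concept_id,
        start_date=event.start_date,
        value_as_concept_id=value_concept_id,
        source_key=event.source_key,
        derived=True,
    )
    pair = output.link(event, obs, relationship_concept_id)
    return obs, pair


def map_disposition(
    rec: SDTMRecord,
    person_id: int,
    date: dt.date,
    config: MappingConfig,
    store: VocabularyStore,
    output: CdmOutput,
) -> Optional[EventRecord]:
    """Map an enrollment / consent / discontinuation record.

    The observation concept per category comes from configuration (several
    standard alternatives exist); enrollment and consent carry the study
    name in value_as_string, discontinuation carries the reason as
    value_as_concept_id when it resolves.
    """
    category = (rec.values.get("DSDECOD") or "").strip().upper()
    key = {
        "ENROLLMENT": "enrollment",
        "CONSENT": "consent",
        "COMPLETION": "completion",
        "WITHDRAWAL": "withdrawal",
    }.get(category)
    if key is None:
        return None
    concept_id = config.disposition_concepts[key]
    value_string = None
    value_concept = None
    if key in ("enrollment", "consent"):
        value_string = config.study_id
    else:
        reason = (rec.values.get("DSREAS") or "").strip().upper()
        if reason:
            targets, _ = store.resolve_source("DSREAS", reason)
            value_concept = targets[0] if targets else None
    return output.new_event(
        "observation",
        person_id=person_id,
        concept_id=concept_id,
        start_date=date,
        value_as_string=value_string,
        value_as_concept_id=value_concept,
        source_value=category,
        source_key=rec.key,
    )


def map_outcome(
    event: EventRecord,
    outcome_value_concept_id: int,
    output: CdmOutput,
    relationship_concept_id: int,
) -> Tuple[EventRecord, Tuple[FactRelationship, FactRelationship]]:
    """Record a non-fatal outcome as a linked outcome-category observation.

    Fatal outcomes never reach here: they are forwarded as death-date
    candidates instead.
    """
    obs = output.new_event(
        "observation",
        person_id=event.person_id,
        concept_id=OUTCOME_CATEGORY_ID,
        start_date=event.start_date,
        value_as_concept_id=outcome_value_concept_id,
        source_key=event.source_key,
        derived=True,
    )
    pair = output.link(event, obs, relationship_concept_id)
    return obs, pair


def emit_combination(
    combo: ConceptCombination,
    store: VocabularyStore,
    person_id: int,
    date: dt.date,
    output: CdmOutput,
    relationship_concept_id: int,
    source_value: str = "",
) -> List[EventRecord]:
    """Emit a combination recipe: primary row plus linked qualifier rows."""
    rows: List[EventRecord] = []
    for cid in combo.concept_ids:
        concept = store.concepts[cid]
        rows.append(
            output.new_event(
                DOMAIN_TO_TABLE[concept.domain_id],
                person_id=person_id,
                concept_id=cid,
                start_date=date,
                source_value=source_value,
            )
        )
    for qualifier_row in rows[1:]:
        output.link(rows[0], qualifier_row, relationship_concept_id)
    return rows


def derive_observation_period(
    person_id: int,
    events: Sequence[EventRecord],
    death_date: Optional[dt.date],
) -> Tuple[int, dt.date, dt.date]:
    """One observation period per person spanning all their dated facts."""
    if not events and death_date is None:
        raise ValueError(f"person {person_id} has no dated event")
    dates = [e.start_date for e in events]
    dates += [e.end_date for e in events if e.end_date is not None]
    if death_date is not None:
        dates.append(death_date)
    return person_id, min(dates), max(dates)


# ---------------------------------------------------------------------------
# the full conversion
# ---------------------------------------------------------------------------

def run_mapping(
    study: StudyDataset, store: VocabularyStore, config: MappingConfig
) -> CdmOutput:
    """Run the complete SDTM-to-CDM conversion of one study."""
    problems = store.lint_crosswalk_domains()
    if problems:
        raise ValueError("vocabulary lint failed: " + "; ".join(problems[:5]))

    output = CdmOutput()
    retained, report, exclusion_log = select_sample(study)
    output.exclusion_report = report
    output.exclusion_log = exclusion_log
    retained_set = set(retained)

    dm_first: Dict[str, SDTMRecord] = {}
    for rec in study.tables["DM"]:
        dm_first.setdefault(rec.patient_id, rec)

    person_ids = {pid: i + 1 for i, pid in enumerate(sorted(retained))}
    for pid in sorted(retained):
        rec = dm_first[pid]
        sex = (rec.values.get("SEX") or "").strip().upper()
        output.persons.append(
            PersonRecord(
                person_id=person_ids[pid],
                source_patient_id=pid,
                year_of_birth=_birth_year(rec),
                gender_concept_id=GENDER_CONCEPT_IDS.get(sex, 0),
                gender_source_value=sex,
            )
        )

    timelines = _build_timelines(study, retained_set, config)

    rel_characteristic = store.register_custom_concept(
        HAS_CHARACTERISTIC_NAME, "Metadata", []
    )
    rel_entity = store.register_custom_concept(
        "Relationship to <entity>", "Observation", []
    )

    kept_by_domain: Dict[str, List[SDTMRecord]] = {}
    for domain in EVENT_DOMAINS + ("DS", "DD"):
        table = study.tables.get(domain)
        if table is None:
            continue
        subset = DomainTable(
            domain, [r for r in table if r.patient_id in retained_set], table.columns
        )
        kept, dropped = filter_non_events(subset)
        kept_by_domain[domain] = kept
        for rec, reason in dropped:
            output.non_event_log.append((rec.patient_id, domain, rec.seq, reason))

    prev_ex_end: Dict[Tuple[str, str], dt.date] = {}
    for domain in EVENT_DOMAINS:
        for rec in sorted(
            kept_by_domain.get(domain, []), key=lambda r: (r.patient_id, r.seq)
        ):
            _process_event_record(
                rec, domain, store, config, timelines[rec.patient_id],
                person_ids[rec.patient_id], output,
                rel_characteristic, rel_entity, prev_ex_end,
            )

    for rec in sorted(
        kept_by_domain.get("DS", []), key=lambda r: (r.patient_id, r.seq)
    ):
        date = _record_date(rec, output, allow_generic=True)
        if date is None:
            output.undatable_log.append(
                (rec.patient_id, "DS", rec.seq, "no_usable_date")
            )
            continue
        emitted = map_disposition(
            rec, person_ids[rec.patient_id], date, config, store, output
        )
        if emitted is None:
            output.unmapped_log.append(
                (
                    rec.patient_id, "DS", rec.seq, "DSDECOD",
                    (rec.values.get("DSDECOD") or "").strip(),
                )
            )

    _process_deaths(
        kept_by_domain.get("DD", []), store, timelines, person_ids, output
    )

    events_by_person: Dict[int, List[EventRecord]] = {}
    for event in output.all_events():
        events_by_person.setdefault(event.person_id, []).append(event)
    death_by_person = {d.person_id: d.death_date for d in output.deaths}
    period_id = 0
    for pid in sorted(retained):
        person_id = person_ids[pid]
        events = events_by_person.get(person_id, [])
        death = death_by_person.get(person_id)
        if not events and death is None:
            continue
        period_id += 1
        _, start, end = derive_observation_period(person_id, events, death)
        output.observation_periods.append((period_id, person_id, start, end))
    return output


def _build_timelines(
    study: StudyDataset, retained: set, config: MappingConfig
) -> Dict[str, ReferenceTimeline]:
    """Assemble per-patient reference time points from the raw tables."""
    timelines: Dict[str, ReferenceTimeline] = {}
    study_end = config.study_end()
    for pid in retained:
        timelines[pid] = ReferenceTimeline(pid, study_end=study_end)

    dm_seen = set()
    for rec in study.tables["DM"]:
        if rec.patient_id not in retained or rec.patient_id in dm_seen:
            continue
        dm_seen.add(rec.patient_id)
        enrol = rec.values.get("RFSTDTC", "").strip()
        if len(enrol) == 10:
            try:
                timelines[rec.patient_id].enrollment = dt.date.fromisoformat(enrol)
            except ValueError:
                pass

    ex = study.tables.get("EX")
    if ex is not None:
        for rec in sorted(ex.records, key=lambda r: (r.patient_id, r.seq)):
            if rec.patient_id not in retained:
                continue
            tl = timelines[rec.patient_id]
            if tl.drug_initiation is None and rec.start_date is not None:
                tl.drug_initiation = rec.start_date
            if rec.end_date is not None:
                tl.drug_end = rec.end_date

    # last available information: latest complete recorded date outside DD
    for domain, table in study.tables.items():
        if domain == "DD":
            continue
        for rec in table:
            if rec.patient_id not in retained:
                continue
            tl = timelines[rec.patient_id]
            for partial in (rec.start_date, rec.end_date):
                if partial is None or not partial.is_complete:
                    continue
                d = partial.to_date()
                if study_end is not None and d > study_end:
                    continue
                if tl.last_available_info is None or d > tl.last_available_info:
                    tl.last_available_info = d

    # death candidates: DD rows by source, plus fatal adverse events
    dd = study.tables.get("DD")
    if dd is not None:
        for rec in dd:
            if rec.patient_id not in retained or rec.start_date is None:
                continue
            source = (
                "safety_db"
                if (rec.values.get("DDSRC") or "").strip().upper() == "SAFETY"
                else "crf_death_details"
            )
            timelines[rec.patient_id].death_candidates.append(
                DeathCandidate(source, rec.start_date)
            )
    ae = study.tables.get("AE")
    if ae is not None:
        for rec in ae:
            if rec.patient_id not in retained:
                continue
            if (rec.values.get("AEOUT") or "").strip().upper() != "FATAL":
                continue
            date = rec.end_date or rec.start_date
            if date is not None:
                timelines[rec.patient_id].death_candidates.append(
                    DeathCandidate("crf_fatal_ae", date)
                )
    return timelines


def _record_date(
    rec: SDTMRecord, output: CdmOutput, allow_generic: bool = True
) -> Optional[dt.date]:
    """Simple date path for disposition records (complete or generic)."""
    partial = rec.start_date
    if partial is None:
        return None
    if partial.is_complete:
        return partial.to_date()
    if not allow_generic:
        return None
    date = impute_generic(partial)
    output.record_audit(
        rec.key,
        ImputationResult(partial, date, "reference_comparison", "generic completion"),
    )
    return date


def _resolve(
    rec: SDTMRecord, store: VocabularyStore
) -> Tuple[List[int], Optional[str], str, str]:
    """Resolve a record's coded term or free text; returns targets + value."""
    if rec.coded_term is not None:
        vocab, code = rec.coded_term
        targets, provenance = store.resolve_source(vocab, code)
        return targets, provenance, vocab, code
    if rec.free_text:
        targets, provenance = store.resolve_source("free-text", rec.free_text)
        return targets, provenance, "free-text", rec.free_text
    return [], None, "", ""


def _start_partial(rec: SDTMRecord, output: CdmOutput) -> Optional[PartialDate]:
    """The record's start date, recovering free-text dates when possible."""
    if rec.start_date is not None:
        return rec.start_date
    for var, text in rec.date_parse_errors:
        if var.endswith("STDTC"):
            extracted = extract_date_from_text(text)
            if extracted is not None:
                return extracted
    return None


def _process_event_record(
    rec: SDTMRecord,
    domain: str,
    store: VocabularyStore,
    config: MappingConfig,
    timeline: ReferenceTimeline,
    person_id: int,
    output: CdmOutput,
    rel_characteristic: int,
    rel_entity: int,
    prev_ex_end: Dict[Tuple[str, str], dt.date],
) -> None:
    targets, provenance, vocab, value = _resolve(rec, store)
    if not targets:
        output.unmapped_log.append((rec.patient_id, domain, rec.seq, vocab, value))
        return

    was_free_text_date = rec.start_date is None and any(
        var.endswith("STDTC") for var, _ in rec.date_parse_errors
    )
    partial = _start_partial(rec, output)

    # -- complete the start date ------------------------------------------
    try:
        if domain == "EX":
            drug_key = (rec.patient_id, value)
            if partial is None:
                raise UnresolvableDateError("drug start date completely missing")
            result = impute_drug_start(partial, prev_ex_end.get(drug_key))
        elif domain == "LB":
            result = impute_lab_date(partial, rec.timepoint, timeline)
        elif partial is not None:
            if partial.is_complete:
                result = ImputationResult(partial, partial.to_date(), None)
            else:
                result = ImputationResult(
                    partial, impute_generic(partial),
                    "reference_comparison", "generic completion",
                )
        else:
            anchored = (
                impute_by_timepoint(rec.timepoint, timeline, config)
                if rec.timepoint
                else None
            )
            if anchored is None:
                raise UnresolvableDateError("no year and no timepoint anchor")
            result = ImputationResult(
                None, anchored, "timepoint", f"timepoint {rec.timepoint!r}"
            )
    except UnresolvableDateError:
        output.undatable_log.append(
            (rec.patient_id, domain, rec.seq, "no_usable_date")
        )
        return
    if was_free_text_date and result.strategy is None:
        result = ImputationResult(
            result.original, result.imputed, "free_text",
            "date extracted from free text",
        )
    output.record_audit(rec.key, result)
    start = result.imputed

    end: Optional[dt.date] = None
    if rec.end_date is not None:
        if rec.end_date.is_complete:
            end = rec.end_date.to_date()
        else:
            end = impute_generic(rec.end_date)
            output.record_audit(
                rec.key,
                ImputationResult(
                    rec.end_date, end, "reference_comparison",
                    "generic completion (end date)",
                ),
            )
        if end < start:
            end = start
    if domain == "EX":
        prev_ex_end[(rec.patient_id, value)] = end or start

    emitted = route_record(rec, targets, store, person_id, start, end, output)
    primary = emitted[0]

    # -- numeric results and units ----------------------------------------
    orres = (rec.values.get(f"{domain}ORRES") or "").strip()
    if domain in ("LB", "VS", "XP") and orres:
        try:
            number = float(orres)
        except ValueError:
            number = None
        for event in emitted:
            if event.table == "measurement":
                event.value_as_number = number
                if domain == "XP" and value == "MPAP":
                    event.unit_concept_id = 8876
            elif event.table == "observation" and number is None:
                # e.g. WHO functional class grade as a value concept
                grade_targets, _ = store.resolve_source("WHOFC", orres)
                if grade_targets:
                    event.value_as_concept_id = grade_targets[0]
                else:
                    event.value_as_string = orres

    # -- linked characteristics, methods and outcomes ---------------------
    severity = (rec.values.get("AESEV") or "").strip().upper()
    if domain == "AE" and severity in SEVERITY_VALUE_IDS:
        attach_characteristic(
            primary, CONDITION_SEVERITY_ID, SEVERITY_VALUE_IDS[severity],
            output, rel_characteristic,
        )
    causality = (rec.values.get("AEREL") or "").strip().upper()
    if domain == "AE" and causality in CAUSALITY_VALUE_IDS:
        attach_characteristic(
            primary, rel_entity, CAUSALITY_VALUE_IDS[causality],
            output, rel_characteristic,
        )
    outcome = (rec.values.get("AEOUT") or "").strip().upper()
    if domain == "AE" and outcome in OUTCOME_VALUE_IDS:
        map_outcome(primary, OUTCOME_VALUE_IDS[outcome], output, rel_characteristic)
    method = (rec.values.get("XPMETHOD") or "").strip().upper()
    if domain == "XP" and method == "THERMODILUTION":
        attach_characteristic(
            primary, THERMODILUTION_ID, None, output, MEASUREMENT_METHOD_REL_ID
        )


def _process_deaths(
    dd_records: Sequence[SDTMRecord],
    store: VocabularyStore,
    timelines: Dict[str, ReferenceTimeline],
    person_ids: Dict[str, int],
    output: CdmOutput,
) -> None:
    """Emit at most one DEATH row per patient with a recorded death."""
    dd_by_patient: Dict[str, List[SDTMRecord]] = {}
    for rec in dd_records:
        dd_by_patient.setdefault(rec.patient_id, []).append(rec)

    dead_patients = sorted(
        set(dd_by_patient)
        | {pid for pid, tl in timelines.items() if tl.death_candidates}
    )
    for pid in dead_patients:
        if pid not in person_ids:
            continue
        tl = timelines[pid]
        try:
            result = impute_death_date(tl.death_candidates, tl.last_available_info)
        except UnresolvableDateError:
            for rec in dd_by_patient.get(pid, []):
                output.undatable_log.append(
                    (pid, "DD", rec.seq, "death_not_placeable")
                )
            continue
        output.record_audit((pid, "DD", 1), result)
        cause_concept = None
        cause_value = None
        for rec in dd_by_patient.get(pid, []):
            targets, _, _, value = _resolve(rec, store)
            if targets:
                cause_concept, cause_value = targets[0], value
                break
        output.deaths.append(
            DeathRecord(person_ids[pid], result.imputed, cause_concept, cause_value)
        )


def read_cdm_output(dir_path: Path | str) -> CdmOutput:
    """Reconstruct a :class:`CdmOutput` from a written output directory.

    Reads the CDM tables, the lineage sidecar (provenance.csv) and the
    logs, so that quality assessment can be recomputed from files exactly
    as from the in-memory result.
    """
    dir_path = Path(dir_path)
    output = CdmOutput()

    def _rows(name: str):
        path = dir_path / name
        if not path.exists():
            return []
        with path.open(newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))

    for row in _rows("PERSON.csv"):
        output.persons.append(
            PersonRecord(
                int(row["person_id"]), row["person_source_value"],
                int(row["year_of_birth"]), int(row["gender_concept_id"]),
                row["gender_source_value"],
            )
        )
    provenance: Dict[Tuple[str, int], Tuple[Optional[Tuple[str, str, int]], bool]] = {}
    for row in _rows("provenance.csv"):
        key = None
        if row["patient_id"]:
            key = (row["patient_id"], row["domain"], int(row["seq"]))
        provenance[(row["table"], int(row["event_id"]))] = (
            key, row["derived"] == "1"
        )
    prefixes = {
        "condition_occurrence": "condition",
        "drug_exposure": "drug",
        "measurement": "measurement",
        "observation": "observation",
        "procedure_occurrence": "procedure",
        "visit_occurrence": "visit",
    }
    for table, p in prefixes.items():
        for row in _rows(f"{table.upper()}.csv"):
            key, derived = provenance.get(
                (table, int(row[f"{table}_id"])), (None, False)
            )
            output.events[table].append(
                EventRecord(
                    event_id=int(row[f"{table}_id"]),
                    person_id=int(row["person_id"]),
                    table=table,
                    concept_id=int(row[f"{p}_concept_id"]),
                    start_date=dt.date.fromisoformat(row[f"{p}_start_date"]),
                    end_date=(
                        dt.date.fromisoformat(row[f"{p}_end_date"])
                        if row[f"{p}_end_date"] else None
                    ),
                    value_as_concept_id=(
                        int(row["value_as_concept_id"])
                        if row["value_as_concept_id"] else None
                    ),
                    value_as_number=(
                        float(row["value_as_number"])
                        if row["value_as_number"] else None
                    ),
                    value_as_string=row["value_as_string"] or None,
                    unit_concept_id=(
                        int(row["unit_concept_id"])
                        if row["unit_concept_id"] else None
                    ),
                    source_value=row[f"{p}_source_value"],
                    source_concept_id=(
                        int(row[f"{p}_source_concept_id"])
                        if row[f"{p}_source_concept_id"] else None
                    ),
                    source_key=key,
                    derived=derived,
                )
            )
    for row in _rows("DEATH.csv"):
        output.deaths.append(
            DeathRecord(
                int(row["person_id"]),
                dt.date.fromisoformat(row["death_date"]),
                int(row["cause_concept_id"]) if row["cause_concept_id"] else None,
                row["cause_source_value"] or None,
            )
        )
    for row in _rows("FACT_RELATIONSHIP.csv"):
        output.fact_relationships.append(
            FactRelationship(
                int(row["domain_concept_id_1"]), int(row["fact_id_1"]),
                int(row["domain_concept_id_2"]), int(row["fact_id_2"]),
                int(row["relationship_concept_id"]),
            )
        )
    output.exclusion_log = [
        (r["patient_id"], r["reason"]) for r in _rows("exclusion_log.csv")
    ]
    output.non_event_log = [
        (r["patient_id"], r["domain"], int(r["seq"]), r["reason"])
        for r in _rows("non_event_log.csv")
    ]
    output.unmapped_log = [
        (r["patient_id"], r["domain"], int(r["seq"]), r["vocabulary"],
         r["source_value"])
        for r in _rows("unmapped_log.csv")
    ]
    output.undatable_log = [
        (r["patient_id"], r["domain"], int(r["seq"]), r["reason"])
        for r in _rows("undatable_log.csv")
    ]
    output.imputation_audit = [
        (r["patient_id"], r["domain"], int(r["seq"]), r["original"],
         r["imputed"], r["strategy"], r["notes"])
        for r in _rows("imputation_audit.csv")
    ]
    for row in _rows("exclusion_report.csv"):
        output.exclusion_report = ExclusionReport(
            int(row["n_in_database"]), int(row["n_violators"]),
            int(row["n_mapping_excluded"]),
        )
    for row in _rows("OBSERVATION_PERIOD.csv"):
        output.observation_periods.append(
            (
                int(row["observation_period_id"]), int(row["person_id"]),
                dt.date.fromisoformat(row["observation_period_start_date"]),
                dt.date.fromisoformat(row["observation_period_end_date"]),
            )
        )
    return output
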