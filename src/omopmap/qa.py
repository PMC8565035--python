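"""Mapping quality assessment: source-vs-CDM accounting and consistency.

After a conversion, three questions decide whether the mapping can be
trusted: did any patient or record disappear without a logged reason; how
much consolidation happened (many source wordings collapsing onto one
standard concept is expected, silent loss is not); and do simple summary
statistics (age at enrollment, gender distribution) agree between the
source tables and the CDM.  The accounting surfaces here mirror the
two standard report shapes of such conversions: a patient-level exclusion
table (database total, violators, mapping exclusions, mapped) and a
per-category count table (unique source values, unique concept ids, custom
concept ids, source records, CDM records, mapped source records) for
condition codes and drug codes.

Definitions (the natural keys, fixed here since report tables rarely spell
them out): a *unique source record* is a distinct (patient, domain,
sequence) triple; a *unique CDM record* is a distinct emitted event row —
counted after one-to-many fan-out, so it can exceed the source-record
count; a *unique source value* is a distinct (vocabulary,
code-or-normalized-text) pair.
"""

from __future__ import annotations

import datetime as dt
import json
import statistics
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .etl import CdmOutput, ExclusionReport
from .sdtm import SDTMRecord, StudyDataset

__all__ = [
    "QACounts",
    "DemographicComparison",
    "QAReport",
    "round_half_up",
    "redundancy_pct",
    "exclusion_accounting",
    "aggregate_counts",
    "compute_qa_counts",
    "consistency_check",
    "compute_qa_report",
]

#: which SDTM domains feed each report category
CATEGORY_DOMAINS: Dict[str, Tuple[str, ...]] = {
    "condition": ("AE", "MH"),
    "drug": ("CM", "EX"),
}


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the rounding convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    result = float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    return result if ndigits > 0 else int(result)


def redundancy_pct(n_source_values: int, n_concept_ids: int) -> Optional[int]:
    """Percentage of source values consolidated onto an existing concept.

    Distinct source wordings of the same clinical entity map to one
    standard concept; the redundancy is (values - concepts) / values,
    rounded to the nearest integer percent.  Zero source values makes the
    quantity undefined (returned as None, reported not-applicable).
    """
    if n_source_values == 0:
        return None
    if n_source_values < n_concept_ids:
        raise ValueError(
            f"more concept ids ({n_concept_ids}) than source values "
            f"({n_source_values})"
        )
    return round_half_up(
        100.0 * (n_source_values - n_concept_ids) / n_source_values
    )


def exclusion_accounting(
    n_db: int, n_violators: int, n_excluded: int
) -> Tuple[int, float]:
    """Patient accounting: (n mapped, percent mapped to one decimal)."""
    n_mapped = n_db - n_violators - n_excluded
    if n_mapped < 0:
        raise ValueError(
            f"negative mapped count: {n_db} - {n_violators} - {n_excluded}"
        )
    return n_mapped, round_half_up(100.0 * n_mapped / n_db, 1)


@dataclass
class QACounts:
    category: str  # condition | drug
    n_unique_source_values: int = 0
    n_unique_concept_ids: int = 0
    n_unique_custom_concept_ids: int = 0
    n_unique_source_records: int = 0
    n_unique_cdm_records: int = 0
    n_unique_source_records_mapped: int = 0
    n_non_event: int = 0
    n_unmapped: int = 0
    n_undatable: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name != "category" and value < 0:
                raise ValueError(f"negative count {name}={value}")
        if self.n_unique_custom_concept_ids > self.n_unique_concept_ids:
            raise ValueError("custom concept ids exceed total concept ids")


def aggregate_counts(reports: List[QACounts]) -> QACounts:
    """Element-wise totals across registries; categories must agree."""
    if not reports:
        return QACounts(category="")
    categories = {r.category for r in reports}
    if len(categories) > 1:
        raise ValueError(f"mixed categories: {sorted(categories)}")
    total = QACounts(category=reports[0].category)
    for name in vars(total):
        if name == "category":
            continue
        setattr(total, name, sum(getattr(r, name) for r in reports))
    return total


def _source_value_key(rec: SDTMRecord) -> Optional[Tuple[str, str]]:
    if rec.coded_term is not None:
        return rec.coded_term
    if rec.free_text:
        return ("free-text", " ".join(rec.free_text.split()).casefold())
    return None


def compute_qa_counts(
    study: StudyDataset, output: CdmOutput, category: str
) -> QACounts:
    """Recompute the count table for one category from a finished run."""
    domains = CATEGORY_DOMAINS[category]
    retained = {p.source_patient_id for p in output.persons}

    source_values = set()
    source_records = set()
    for domain in domains:
        table = study.tables.get(domain)
        if table is None:
            continue
        for rec in table:
            if rec.patient_id not in retained:
                continue
            source_records.add(rec.key)
            key = _source_value_key(rec)
            if key is not None:
                source_values.add(key)

    concept_ids = set()
    mapped_records = set()
    n_cdm = 0
    for event in output.all_events():
        if event.source_key is None or event.source_key[1] not in domains:
            continue
        if event.derived:
            # linked characteristics/outcomes are by-products of another
            # event, not mappings of the source record's own term
            continue
        n_cdm += 1
        concept_ids.add(event.concept_id)
        mapped_records.add(event.source_key)

    def _count_log(log, idx_domain=1):
        return sum(1 for row in log if row[idx_domain] in domains)

    return QACounts(
        category=category,
        n_unique_source_values=len(source_values),
        n_unique_concept_ids=len(concept_ids),
        n_unique_custom_concept_ids=sum(
            1 for c in concept_ids if c >= 2_000_000_000
        ),
        n_unique_source_records=len(source_records),
        n_unique_cdm_records=n_cdm,
        n_unique_source_records_mapped=len(mapped_records),
        n_non_event=_count_log(output.non_event_log),
        n_unmapped=_count_log(output.unmapped_log),
        n_undatable=_count_log(output.undatable_log),
    )


@dataclass
class DemographicComparison:
    """Mean (SD) age at enrollment and gender split, both sides."""

    n_sdtm: int
    n_cdm: int
    age_mean_sdtm: Optional[float]
    age_mean_cdm: Optional[float]
    age_sd_sdtm: Optional[float]
    age_sd_cdm: Optional[float]
    gender_counts_sdtm: Dict[str, int]
    gender_counts_cdm: Dict[str, int]
    flags: List[str] = field(default_factory=list)


_GENDER_BY_CONCEPT = {8507: "M", 8532: "F"}


def consistency_check(
    study: StudyDataset, output: CdmOutput
) -> DemographicComparison:
    """Compare demographics computed independently on both sides.

    Ages at enrollment (enrollment year minus birth year) and gender counts
    are derived once from the source DM rows and once from the CDM PERSON
    rows, over mapped patients only.  The source-side cohort comes from DM
    minus the exclusion log — independently of the PERSON table — so a
    person row lost in serialization is caught.  Counts must agree exactly;
    means and SDs within 0.01.  Any discrepancy raises a flag, never an
    exception.
    """
    excluded = {pid for pid, reason in output.exclusion_log
                if reason != "duplicate_row"}
    sdtm_ages: List[float] = []
    sdtm_gender: Dict[str, int] = {}
    seen = set()
    for rec in study.tables["DM"]:
        if rec.patient_id in excluded or rec.patient_id in seen:
            continue
        seen.add(rec.patient_id)
        sex = (rec.values.get("SEX") or "").strip().upper() or "UNK"
        sdtm_gender[sex] = sdtm_gender.get(sex, 0) + 1
        birth = (rec.values.get("BRTHDTC") or "").strip()[:4]
        enrol = (rec.values.get("RFSTDTC") or "").strip()[:4]
        if birth.isdigit() and enrol.isdigit():
            sdtm_ages.append(int(enrol) - int(birth))

    enrol_year: Dict[int, int] = {}
    for event in output.events["observation"]:
        if event.source_key is not None and event.source_key[1] == "DS":
            enrol_year.setdefault(event.person_id, event.start_date.year)
    cdm_ages: List[float] = []
    cdm_gender: Dict[str, int] = {}
    for person in output.persons:
        g = _GENDER_BY_CONCEPT.get(person.gender_concept_id, "UNK")
        cdm_gender[g] = cdm_gender.get(g, 0) + 1
        year = enrol_year.get(person.person_id)
        if year is not None:
            cdm_ages.append(year - person.year_of_birth)

    def _mean_sd(xs: List[float]) -> Tuple[Optional[float], Optional[float]]:
        if not xs:
            return None, None
        mean = statistics.fmean(xs)
        sd = statistics.stdev(xs) if len(xs) > 1 else 0.0
        return mean, sd

    mean_s, sd_s = _mean_sd(sdtm_ages)
    mean_c, sd_c = _mean_sd(cdm_ages)
    comparison = DemographicComparison(
        n_sdtm=len(seen),
        n_cdm=len(output.persons),
        age_mean_sdtm=mean_s,
        age_mean_cdm=mean_c,
        age_sd_sdtm=sd_s,
        age_sd_cdm=sd_c,
        gender_counts_sdtm=sdtm_gender,
        gender_counts_cdm=cdm_gender,
    )
    if comparison.n_sdtm != comparison.n_cdm:
        comparison.flags.append(
            f"person count mismatch: {comparison.n_sdtm} SDTM vs "
            f"{comparison.n_cdm} CDM"
        )
    if sdtm_gender != cdm_gender:
        comparison.flags.append(
            f"gender distribution mismatch: {sdtm_gender} vs {cdm_gender}"
        )
    for label, a, b in (("mean age", mean_s, mean_c), ("age SD", sd_s, sd_c)):
        if a is not None and b is not None and abs(a - b) > 0.01:
            comparison.flags.append(f"{label} differs: {a:.4f} vs {b:.4f}")
        elif (a is None) != (b is None):
            comparison.flags.append(f"{label} computable on one side only")
    return comparison


@dataclass
class QAReport:
    study_id: str
    exclusion: Dict[str, float]
    counts: Dict[str, QACounts]
    redundancy_pct: Dict[str, Optional[int]]
    mapping_rate_pct: Dict[str, Optional[float]]
    mapping_rate_excl_non_events_pct: Dict[str, Optional[float]]
    demographics: DemographicComparison

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path: Path | str) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def compute_qa_report(study: StudyDataset, output: CdmOutput) -> QAReport:
    """Assemble the full quality-assessment report for one finished run."""
    report = output.exclusion_report
    if report is None:
        raise ValueError("conversion output carries no exclusion report")
    counts = {
        cat: compute_qa_counts(study, output, cat) for cat in CATEGORY_DOMAINS
    }
    rates: Dict[str, Optional[float]] = {}
    rates_excl: Dict[str, Optional[float]] = {}
    for cat, c in counts.items():
        total = c.n_unique_source_records
        rates[cat] = (
            round_half_up(100.0 * c.n_unique_source_records_mapped / total, 1)
            if total
            else None
        )
        denominator = total - c.n_non_event
        rates_excl[cat] = (
            round_half_up(
                100.0 * c.n_unique_source_records_mapped / denominator, 1
            )
            if denominator > 0
            else None
        )
    return QAReport(
        study_id=study.study_id,
        exclusion={
            "n_in_database": report.n_in_database,
            "n_violators": report.n_violators,
            "pct_violators": report.pct_violators,
            "n_mapping_excluded": report.n_mapping_excluded,
            "pct_mapping_excluded": report.pct_mapping_excluded,
            "n_mapped": report.n_mapped,
            "pct_mapped": report.pct_mapped,
        },
        counts=counts,
        redundancy_pct={
            cat: redundancy_pct(
                c.n_unique_source_values, c.n_unique_concept_ids
            )
            if c.n_unique_source_values >= c.n_unique_concept_ids
            else None
            for cat, c in counts.items()
        },
        mapping_rate_pct=rates,
        mapping_rate_excl_non_events_pct=rates_excl,
        demographics=consistency_check(study, output),
    )
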