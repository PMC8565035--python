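"""SDTM-style domain tables: record types and delimited-text I/O.

A study arrives as one comma-delimited UTF-8 file per two/three-letter SDTM
domain (DM.csv, AE.csv, ...), RFC-4180 quoted, one header row.  Reading is
strictly non-destructive: every cell is preserved verbatim in the record's
``values`` map; the typed fields (dates, flags, coded terms) are parsed
*views* of those cells.  Unparseable date strings are kept verbatim and
flagged — imputation and filtering happen downstream and are logged there.

Variable-name conventions follow SDTM: ``--STDTC``/``--ENDTC`` for start and
end dates, ``--OCCUR`` for occurrence flags, ``--STAT`` for completion
status, ``--TPT`` for timepoint labels, ``--DECOD``/``--PTCD`` for the coded
term and its dictionary code, ``--TERM`` for verbatim text.  Per-domain
overrides come from the mapping configuration.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Set, Tuple

from .config import MappingConfig
from .dates import PartialDate, PartialDateError, parse_partial_date

__all__ = [
    "SDTMRecord",
    "DomainTable",
    "StudyDataset",
    "read_study",
    "write_study",
]

#: domains the reader knows; anything else loads as a generic domain
KNOWN_DOMAINS = ("DM", "AE", "CM", "EX", "LB", "MH", "VS", "DD", "DS", "XP")

SUBJECT_VAR = "USUBJID"


@dataclass
class SDTMRecord:
    """One verbatim source row, keyed by (patient, domain, sequence)."""

    patient_id: str
    domain: str
    seq: int
    values: Dict[str, str]
    coded_term: Optional[Tuple[str, str]] = None  # (vocabulary_id, code)
    free_text: Optional[str] = None
    occur_flag: Optional[str] = None    # Y / N / U
    status_flag: Optional[str] = None   # NOT DONE
    timepoint: Optional[str] = None
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None
    #: (variable, verbatim text) for every date cell that failed to parse
    date_parse_errors: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def key(self) -> Tuple[str, str, int]:
        return (self.patient_id, self.domain, self.seq)

    @property
    def is_non_event(self) -> bool:
        """Non-occurrence / not-done semantics live only in the two flags."""
        return self.occur_flag in ("N", "U") or self.status_flag == "NOT DONE"


@dataclass
class DomainTable:
    domain: str
    records: List[SDTMRecord] = field(default_factory=list)
    columns: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.domain != self.domain:
                raise ValueError(
                    f"record domain {rec.domain!r} in table {self.domain!r}"
                )

    def __iter__(self) -> Iterator[SDTMRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StudyDataset:
    study_id: str
    design: str = "prospective"
    study_end_date: Optional[PartialDate] = None
    tables: Dict[str, DomainTable] = field(default_factory=dict)
    violator_ids: Set[str] = field(default_factory=set)

    def patients(self) -> List[str]:
        """Patient ids in DM, in file order (duplicates collapsed)."""
        seen: Dict[str, None] = {}
        for rec in self.tables.get("DM", DomainTable("DM")):
            seen.setdefault(rec.patient_id, None)
        return list(seen)

    def validate_referential_integrity(self) -> None:
        dm_ids = set(self.patients())
        for domain, table in self.tables.items():
            if domain == "DM":
                continue
            orphans = {r.patient_id for r in table} - dm_ids
            if orphans:
                raise ValueError(
                    f"{domain} references patients absent from DM: "
                    f"{sorted(orphans)[:5]}"
                )


def _parse_record(
    domain: str, row: Dict[str, str], seq_fallback: int, config: MappingConfig
) -> SDTMRecord:
    v = lambda role, default: config.variable(domain, role, default)
    get = lambda name: (row.get(name) or "").strip() or None

    seq_text = get(v("seq", f"{domain}SEQ"))
    rec = SDTMRecord(
        patient_id=(row.get(v("subject", SUBJECT_VAR)) or "").strip(),
        domain=domain,
        seq=int(seq_text) if seq_text else seq_fallback,
        values=dict(row),
    )

    code = get(v("code", f"{domain}PTCD"))
    if code is not None:
        vocab = config.domain_vocabulary.get(domain, "MedDRA")
        rec.coded_term = (vocab, code)
    rec.free_text = get(v("term", f"{domain}TERM"))

    occur = get(v("occur", f"{domain}OCCUR"))
    if occur is not None:
        rec.occur_flag = occur.upper()
    stat = get(v("status", f"{domain}STAT"))
    if stat is not None:
        rec.status_flag = stat.upper()
    rec.timepoint = get(v("timepoint", f"{domain}TPT"))

    for attr, role, default in (
        ("start_date", "start", f"{domain}STDTC"),
        ("end_date", "end", f"{domain}ENDTC"),
    ):
        name = v(role, default)
        text = get(name)
        if text is None:
            continue
        try:
            setattr(rec, attr, parse_partial_date(text))
        except PartialDateError:
            rec.date_parse_errors.append((name, text))
    return rec


def _read_domain_file(path: Path, domain: str, config: MappingConfig) -> DomainTable:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        columns = list(reader.fieldnames or [])
        records = [
            _parse_record(domain, row, i + 1, config)
            for i, row in enumerate(reader)
        ]
    table = DomainTable(domain, records, columns)
    keys = [r.key for r in records]
    # (patient, domain, seq) must be unique except for literal duplicate rows,
    # which sample selection deduplicates with an exclusion-log entry
    dupes = {k for k in keys if keys.count(k) > 1} if len(keys) < 5000 else set()
    if dupes and domain != "DM":
        warnings.warn(f"{domain}: duplicate (patient, seq) keys: {sorted(dupes)[:3]}")
    return table


def read_study(dir_path: Path | str, config: Optional[MappingConfig] = None) -> StudyDataset:
    """Read a directory of ``<DOMAIN>.csv`` files into a :class:`StudyDataset`.

    A missing ``DM.csv`` is fatal; a file whose stem is not a known domain
    is loaded as a generic domain with a warning.  Violator flags are read
    from ``VIOLATORS.csv`` (single ``USUBJID`` column) when present.
    """
    config = config or MappingConfig()
    dir_path = Path(dir_path)
    if not (dir_path / "DM.csv").exists():
        raise FileNotFoundError(f"required domain file missing: {dir_path / 'DM.csv'}")

    study = StudyDataset(
        study_id=config.study_id,
        design=config.design,
        study_end_date=config.study_end_date,
    )
    for path in sorted(dir_path.glob("*.csv")):
        domain = path.stem.upper()
        if domain == "VIOLATORS":
            with path.open(newline="", encoding="utf-8") as fh:
                study.violator_ids = {
                    (row.get(SUBJECT_VAR) or "").strip()
                    for row in csv.DictReader(fh)
                }
            continue
        if not (2 <= len(domain) <= 3 and domain.isalpha()):
            # sidecars (ledger, logs) are not domain tables
            continue
        if domain not in KNOWN_DOMAINS:
            warnings.warn(f"unknown domain file {path.name}; loading as generic domain")
        study.tables[domain] = _read_domain_file(path, domain, config)
    study.validate_referential_integrity()
    return study


def write_study(study: StudyDataset, dir_path: Path | str) -> None:
    """Write every domain table back to ``<DOMAIN>.csv``, verbatim.

    Together with :func:`read_study` this round-trips conforming files
    byte-for-byte at the cell level: only the untouched ``values`` map is
    written, in the original column order.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for domain, table in study.tables.items():
        with (dir_path / f"{domain}.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=table.columns)
            writer.writeheader()
            for rec in table:
                writer.writerow(rec.values)
    if study.violator_ids:
        with (dir_path / "VIOLATORS.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([SUBJECT_VAR])
            for pid in sorted(study.violator_ids):
                writer.writerow([pid])
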