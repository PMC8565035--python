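"""Deterministic synthetic SDTM registry fixtures with known ground truth.

Real PH registry databases are proprietary, so the pipeline is exercised
on generated studies that reproduce their *structural* pathologies —
MedDRA-coded conditions and WHODrug-coded medications, free-text entries,
ISO-8601 partial dates, free-text date strings, non-occurrence and NOT
DONE records, duplicate patients, protocol violators, and death dates
recorded in up to three conflicting sources — without any attempt at
clinical realism.  Alongside the domain tables, :func:`generate` emits a
per-record ground-truth ledger (true date, non-event / duplicate /
violator / unmappable flags, expected concept targets), from which
:func:`expected_qa` computes the exact accounting the conversion pipeline
must reproduce.  That closure — pipeline output equals ledger expectation,
record for record — is the generator's whole purpose.

Randomness discipline: each (patient, domain) pair draws from its own
seeded substream, so adding a domain or a field never perturbs the values
generated for another.  Identical config and seed give byte-identical
output files.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import MappingConfig
from .qa import QACounts
from .sdtm import DomainTable, SDTMRecord, StudyDataset, write_study
from .vocabulary import VocabularyStore
from .fixtures import bundled_vocabulary

__all__ = ["GeneratorConfig", "MiniDictionary", "generate", "expected_qa", "ExpectedQA"]

_DOMAIN_STREAM = {
    d: i for i, d in enumerate(
        ("DM", "AE", "CM", "EX", "LB", "MH", "VS", "XP", "DS", "DD"), start=1
    )
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape knobs of the synthetic registry.

    The defaults describe a mid-sized prospective drug registry: a few
    thousand to a few hundred patients, one to two percent protocol
    violators and duplicate entries, roughly one record in ten with a
    missing day, one in twenty missing day and month, a few percent with
    no date at all, and — in prospective mode — a condition checklist
    where about half the items are ticked 'did not occur'.
    """

    n_patients: int = 500
    design: str = "prospective"  # or "retrospective"
    seed: int = 42
    study_id: str = "SYNTH"
    rate_missing_day: float = 0.10
    rate_missing_month_day: float = 0.05
    rate_fully_missing_date: float = 0.03
    rate_non_occurrence: float = 0.5
    rate_not_done: float = 0.05
    rate_duplicates: float = 0.02
    rate_violators: float = 0.02
    death_rate: float = 0.06
    rate_conflicting_death_sources: float = 0.4
    rate_free_text: float = 0.10
    rate_unmappable: float = 0.03
    rate_missing_birth_year: float = 0.01
    rate_missing_treatment_dates: float = 0.01
    study_start: dt.date = dt.date(2015, 1, 1)
    study_end: dt.date = dt.date(2020, 12, 31)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name.startswith(("rate_", "death_")):
                value = getattr(self, f.name)
                if not (0.0 <= value <= 1.0):
                    raise ValueError(f"{f.name}={value} outside [0, 1]")
        if self.design not in ("prospective", "retrospective"):
            raise ValueError(f"unknown design {self.design!r}")

    def mapping_config(self) -> MappingConfig:
        from .dates import PartialDate

        return MappingConfig(
            study_id=self.study_id,
            design=self.design,
            study_end_date=PartialDate.from_date(self.study_end),
        )


@dataclass
class MiniDictionary:
    """The small coding universe the generator draws from.

    Built from the bundled vocabulary's crosswalk so that every 'mappable'
    code really resolves and every 'unmappable' one really does not.
    """

    meddra_codes: List[Tuple[str, str]]          # (code, preferred term)
    checklist_codes: List[Tuple[str, str]]       # prospective MH checklist
    cause_of_death_codes: List[Tuple[str, str]]
    drug_codes: List[Tuple[str, str]]            # (WHODrug-like code, name)
    free_text_conditions: List[str]
    free_text_drugs: List[str]
    lab_tests: List[str]
    vs_tests: List[str]
    timepoints: List[str]
    unmappable_meddra: str = "10999999"
    unmappable_drug: str = "WD999999"
    unmappable_text: str = "zzz-nonsense entry"
    targets: Dict[Tuple[str, str], Tuple[int, ...]] = field(default_factory=dict)

    @classmethod
    def from_store(cls, store: VocabularyStore) -> "MiniDictionary":
        targets = {
            key: entry.target_concept_ids for key, entry in store.crosswalk.items()
        }
        meddra = sorted(
            (c.concept_code, c.name)
            for c in store.concepts.values()
            if c.vocabulary_id == "MedDRA"
        )
        drugs = sorted(
            (c.concept_code, c.name.replace(" (WHODrug)", ""))
            for c in store.concepts.values()
            if c.vocabulary_id == "WHODrug"
        )
        checklist = [m for m in meddra if m[0] in (
            "10051297", "10013968", "10002034", "10042772", "10020772", "10012601"
        )]
        return cls(
            meddra_codes=meddra,
            checklist_codes=checklist,
            cause_of_death_codes=[m for m in meddra if m[0] in ("10019279", "10064911")],
            drug_codes=drugs,
            free_text_conditions=[
                "swelling of both ankles",
                "short of breath on exertion",
                "drug- and toxin-induced PAH",
                "PH with unclear and/or multifactorial mechanisms",
            ],
            free_text_drugs=["macitentan 10 mg", "selexipag tablets", "lasix"],
            lab_tests=["NTPROBNP", "CREAT", "HGB", "ALT"],
            vs_tests=["SYSBP", "DIABP", "HR", "WEIGHT"],
            timepoints=["LAST AVAILABLE"],
            targets=targets,
        )

    def resolve(self, vocab: str, code_or_text: str) -> Tuple[int, ...]:
        key = (vocab, " ".join(code_or_text.split()).casefold())
        return self.targets.get(key, ())


@dataclass
class LedgerRow:
    """Ground truth for one generated source record (or DM patient row)."""

    patient_id: str
    domain: str
    seq: int
    category: str               # condition | drug | other | patient
    true_date: str = ""         # complete ISO date the record refers to
    source_vocab: str = ""
    source_code: str = ""       # normalized like the resolver's lookup key
    targets: Tuple[int, ...] = ()
    non_event: bool = False
    unmappable: bool = False
    undatable: bool = False
    free_text_date: bool = False
    death: bool = False
    excluded_reason: str = ""   # patient rows: why selection drops them

    @property
    def n_targets(self) -> int:
        return len(self.targets)


_MON_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)


class _StudyBuilder:
    def __init__(self, config: GeneratorConfig, dictionary: MiniDictionary):
        self.cfg = config
        self.dict = dictionary
        self.rows: Dict[str, List[Dict[str, str]]] = {d: [] for d in _DOMAIN_STREAM}
        self.ledger: List[LedgerRow] = []
        self.violators: List[str] = []

    def rng(self, patient_index: int, domain: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.cfg.seed, patient_index, _DOMAIN_STREAM[domain]]
        )

    # -- date helpers -----------------------------------------------------

    def _degrade(self, date: dt.date, rng: np.random.Generator,
                 allow_missing: bool = True) -> str:
        """Degrade a complete date per the configured missingness profile."""
        u = rng.random()
        if allow_missing and u < self.cfg.rate_fully_missing_date:
            return ""
        u -= self.cfg.rate_fully_missing_date if allow_missing else 0.0
        if u < self.cfg.rate_missing_month_day:
            return f"{date.year:04d}"
        if u < self.cfg.rate_missing_month_day + self.cfg.rate_missing_day:
            return f"{date.year:04d}-{date.month:02d}"
        return date.isoformat()

    def _rand_date(self, rng: np.random.Generator, start: dt.date,
                   max_days: int) -> dt.date:
        return start + dt.timedelta(days=int(rng.integers(0, max_days + 1)))

    # -- patients ---------------------------------------------------------

    def build(self) -> None:
        for i in range(self.cfg.n_patients):
            self._patient(i)

    def _patient(self, i: int) -> None:
        cfg = self.cfg
        rng = self.rng(i, "DM")
        pid = f"{cfg.study_id}-{i + 1:05d}"
        person_key = f"SP{i + 1:05d}"

        is_violator = rng.random() < cfg.rate_violators
        missing_birth = (not is_violator) and rng.random() < cfg.rate_missing_birth_year
        missing_treatment = (
            not is_violator and not missing_birth
            and rng.random() < cfg.rate_missing_treatment_dates
        )
        has_clone = (
            not is_violator and not missing_birth and not missing_treatment
            and rng.random() < cfg.rate_duplicates
        )
        dies = rng.random() < cfg.death_rate

        birth_year = int(rng.integers(1930, 1986))
        sex = str(rng.choice(["F", "M", ""], p=[0.70, 0.29, 0.01]))
        enrollment = self._rand_date(rng, cfg.study_start, 1100)
        consent = enrollment - dt.timedelta(days=int(rng.integers(0, 31)))
        site = f"S{int(rng.integers(1, 21)):02d}"

        dm_row = {
            "USUBJID": pid,
            "DMSPID": person_key,
            "SITEID": site,
            "BRTHDTC": "" if missing_birth else str(birth_year),
            "SEX": sex,
            "RFSTDTC": enrollment.isoformat(),
            "RFICDTC": consent.isoformat(),
        }
        self.rows["DM"].append(dm_row)
        excluded = (
            "protocol_violator" if is_violator
            else "missing_birth_year" if missing_birth
            else "missing_treatment_dates" if missing_treatment
            else ""
        )
        self.ledger.append(
            LedgerRow(pid, "DM", 1, "patient", enrollment.isoformat(),
                      excluded_reason=excluded, death=dies and not excluded)
        )
        if is_violator:
            self.violators.append(pid)
        if has_clone:
            clone_pid = pid + "D"
            clone_row = dict(dm_row, USUBJID=clone_pid)
            self.rows["DM"].append(clone_row)
            self.ledger.append(
                LedgerRow(clone_pid, "DM", 1, "patient",
                          excluded_reason="duplicate")
            )

        # disposition: everyone enrolls and consents; violators stop there
        self._ds(i, pid, enrollment, consent, is_violator, dies)
        if is_violator:
            return

        death_date = (
            enrollment + dt.timedelta(days=int(rng.integers(100, 901)))
            if dies else None
        )
        drug_end = self._ex(i, pid, enrollment, missing_treatment)
        self._ae(i, pid, enrollment, death_date)
        self._cm(i, pid, enrollment)
        self._lb(i, pid, enrollment)
        self._mh(i, pid, enrollment)
        self._vs(i, pid, enrollment)
        self._xp(i, pid, enrollment)
        if dies:
            self._dd(i, pid, death_date)

    # -- domains ----------------------------------------------------------

    def _ds(self, i: int, pid: str, enrollment: dt.date, consent: dt.date,
            is_violator: bool, dies: bool) -> None:
        rng = self.rng(i, "DS")
        rows = [
            {"USUBJID": pid, "DSSEQ": "1", "DSDECOD": "ENROLLMENT",
             "DSREAS": "", "DSSTDTC": enrollment.isoformat()},
            {"USUBJID": pid, "DSSEQ": "2", "DSDECOD": "CONSENT",
             "DSREAS": "", "DSSTDTC": consent.isoformat()},
        ]
        self.ledger.append(LedgerRow(pid, "DS", 1, "other", enrollment.isoformat()))
        self.ledger.append(LedgerRow(pid, "DS", 2, "other", consent.isoformat()))
        if not is_violator and not dies and rng.random() < 0.3:
            end = enrollment + dt.timedelta(days=int(rng.integers(300, 901)))
            decod = str(rng.choice(["COMPLETION", "WITHDRAWAL"]))
            rows.append(
                {"USUBJID": pid, "DSSEQ": "3", "DSDECOD": decod,
                 "DSREAS": "OTHER" if decod == "WITHDRAWAL" else "",
                 "DSSTDTC": end.isoformat()}
            )
            self.ledger.append(LedgerRow(pid, "DS", 3, "other", end.isoformat()))
        self.rows["DS"].extend(rows)

    def _ex(self, i: int, pid: str, enrollment: dt.date,
            missing_treatment: bool) -> dt.date:
        rng = self.rng(i, "EX")
        code, name = self.dict.drug_codes[int(rng.integers(len(self.dict.drug_codes)))]
        n_intervals = int(rng.integers(1, 4))
        cursor = enrollment
        for seq in range(1, n_intervals + 1):
            start = cursor + dt.timedelta(days=int(rng.integers(1, 61)))
            end = start + dt.timedelta(days=int(rng.integers(30, 201)))
            cursor = end
            start_text = self._degrade(start, rng, allow_missing=False)
            end_text = end.isoformat() if rng.random() > 0.15 else ""
            if missing_treatment:
                start_text = end_text = ""
            self.rows["EX"].append(
                {"USUBJID": pid, "EXSEQ": str(seq), "EXPTCD": code,
                 "EXDECOD": name, "EXSTDTC": start_text, "EXENDTC": end_text}
            )
            self.ledger.append(
                LedgerRow(pid, "EX", seq, "drug", start.isoformat(),
                          "WHODrug", code, self.dict.resolve("WHODrug", code))
            )
        return cursor

    def _source_term(self, rng: np.random.Generator, kind: str
                     ) -> Tuple[str, str, str, str, bool]:
        """Pick (vocab, code, decod, term, unmappable) for a coded/text row."""
        d = self.dict
        if rng.random() < self.cfg.rate_unmappable:
            if kind == "drug":
                return "WHODrug", d.unmappable_drug, "", "", True
            if rng.random() < 0.5:
                return "MedDRA", d.unmappable_meddra, "", "", True
            return "free-text", "", "", d.unmappable_text, True
        if rng.random() < self.cfg.rate_free_text:
            pool = d.free_text_drugs if kind == "drug" else d.free_text_conditions
            term = str(pool[int(rng.integers(len(pool)))])
            return "free-text", "", "", term, False
        if kind == "drug":
            code, name = d.drug_codes[int(rng.integers(len(d.drug_codes)))]
            return "WHODrug", code, name, "", False
        code, name = d.meddra_codes[int(rng.integers(len(d.meddra_codes)))]
        return "MedDRA", code, name, "", False

    def _event_ledger(self, pid: str, domain: str, seq: int, category: str,
                      true_date: dt.date, vocab: str, code: str, term: str,
                      unmappable: bool, date_text: str,
                      free_text_date: bool) -> None:
        source_vocab = vocab if code else "free-text"
        source_code = code if code else " ".join(term.split()).casefold()
        targets = () if unmappable else self.dict.resolve(source_vocab, source_code)
        undatable = (not unmappable) and date_text == "" and not free_text_date
        self.ledger.append(
            LedgerRow(pid, domain, seq, category, true_date.isoformat(),
                      source_vocab, source_code, targets,
                      unmappable=unmappable, undatable=undatable,
                      free_text_date=free_text_date)
        )

    def _ae(self, i: int, pid: str, enrollment: dt.date,
            death_date: Optional[dt.date]) -> None:
        rng = self.rng(i, "AE")
        n = int(rng.integers(0, 6))
        for seq in range(1, n + 1):
            vocab, code, decod, term, unmappable = self._source_term(rng, "condition")
            start = self._rand_date(rng, enrollment, 700)
            has_end = rng.random() < 0.6
            end = start + dt.timedelta(days=int(rng.integers(0, 31)))
            start_text = self._degrade(start, rng)
            free_text_date = False
            if start_text == start.isoformat() and rng.random() < self.cfg.rate_free_text:
                start_text = f"{start.day} {_MON_NAMES[start.month - 1]} {start.year}"
                free_text_date = True
            sev = str(rng.choice(["MILD", "MODERATE", "SEVERE"]))
            rel = str(rng.choice(["Y", "N", "POSSIBLE", "UNLIKELY"]))
            out = str(rng.choice(["RECOVERED", "RECOVERING", "NOT RECOVERED", ""]))
            self.rows["AE"].append(
                {"USUBJID": pid, "AESEQ": str(seq), "AEPTCD": code,
                 "AEDECOD": decod, "AETERM": term, "AESTDTC": start_text,
                 "AEENDTC": end.isoformat() if has_end else "",
                 "AESEV": sev, "AEREL": rel, "AEOUT": out}
            )
            self._event_ledger(pid, "AE", seq, "condition", start, vocab,
                               code, term, unmappable, start_text, free_text_date)
        if death_date is not None:
            seq = n + 1
            code, decod = self.dict.cause_of_death_codes[
                int(rng.integers(len(self.dict.cause_of_death_codes)))
            ]
            end_text = self._degrade(death_date, rng, allow_missing=False)
            self.rows["AE"].append(
                {"USUBJID": pid, "AESEQ": str(seq), "AEPTCD": code,
                 "AEDECOD": decod, "AETERM": "", "AESTDTC": death_date.isoformat(),
                 "AEENDTC": end_text, "AESEV": "SEVERE", "AEREL": "N",
                 "AEOUT": "FATAL"}
            )
            self._event_ledger(pid, "AE", seq, "condition", death_date,
                               "MedDRA", code, "", False,
                               death_date.isoformat(), False)

    def _cm(self, i: int, pid: str, enrollment: dt.date) -> None:
        rng = self.rng(i, "CM")
        n = int(rng.integers(0, 4))
        for seq in range(1, n + 1):
            vocab, code, decod, term, unmappable = self._source_term(rng, "drug")
            start = self._rand_date(rng, enrollment, 700)
            start_text = self._degrade(start, rng)
            end = start + dt.timedelta(days=int(rng.integers(10, 301)))
            self.rows["CM"].append(
                {"USUBJID": pid, "CMSEQ": str(seq), "CMPTCD": code,
                 "CMDECOD": decod, "CMTERM": term, "CMSTDTC": start_text,
                 "CMENDTC": end.isoformat() if rng.random() < 0.5 else ""}
            )
            self._event_ledger(pid, "CM", seq, "drug", start, vocab, code,
                               term, unmappable, start_text, False)

    def _lb(self, i: int, pid: str, enrollment: dt.date) -> None:
        rng = self.rng(i, "LB")
        n = int(rng.integers(1, 5))
        seq = 0
        for _ in range(n):
            seq += 1
            test = str(self.dict.lab_tests[int(rng.integers(len(self.dict.lab_tests)))])
            date = self._rand_date(rng, enrollment, 700)
            date_text = self._degrade(date, rng)
            # a dateless laboratory record always carries an anchorable
            # timepoint label, so it is completed rather than dropped
            tpt = "LAST AVAILABLE" if date_text == "" else (
                "DRUG INITIATION" if rng.random() < 0.1 else ""
            )
            self.rows["LB"].append(
                {"USUBJID": pid, "LBSEQ": str(seq), "LBPTCD": test,
                 "LBORRES": f"{rng.uniform(0.5, 300.0):.1f}", "LBSTAT": "",
                 "LBTPT": tpt, "LBSTDTC": date_text}
            )
            self.ledger.append(
                LedgerRow(pid, "LB", seq, "other", date.isoformat(),
                          "LBTEST", test, self.dict.resolve("LBTEST", test))
            )
        if self.cfg.design == "prospective" and rng.random() < self.cfg.rate_not_done:
            seq += 1
            test = str(self.dict.lab_tests[int(rng.integers(len(self.dict.lab_tests)))])
            date = self._rand_date(rng, enrollment, 700)
            self.rows["LB"].append(
                {"USUBJID": pid, "LBSEQ": str(seq), "LBPTCD": test,
                 "LBORRES": "", "LBSTAT": "NOT DONE", "LBTPT": "",
                 "LBSTDTC": date.isoformat()}
            )
            self.ledger.append(
                LedgerRow(pid, "LB", seq, "other", date.isoformat(),
                          "LBTEST", test, self.dict.resolve("LBTEST", test),
                          non_event=True)
            )

    def _mh(self, i: int, pid: str, enrollment: dt.date) -> None:
        rng = self.rng(i, "MH")
        seq = 0
        # condition checklist: prospective mode records both ticked and
        # unticked items; retrospective chart review captures only events
        # that occurred
        for code, decod in self.dict.checklist_codes:
            occurred = rng.random() >= self.cfg.rate_non_occurrence
            date = enrollment - dt.timedelta(days=int(rng.integers(30, 3000)))
            if self.cfg.design == "retrospective" and not occurred:
                continue
            seq += 1
            date_text = self._degrade(date, rng)
            occur = ("Y" if occurred else "N") if self.cfg.design == "prospective" else ""
            self.rows["MH"].append(
                {"USUBJID": pid, "MHSEQ": str(seq), "MHPTCD": code,
                 "MHDECOD": decod, "MHTERM": "", "MHOCCUR": occur,
                 "MHSTDTC": date_text}
            )
            if not occurred:
                self.ledger.append(
                    LedgerRow(pid, "MH", seq, "condition", date.isoformat(),
                              "MedDRA", code, self.dict.resolve("MedDRA", code),
                              non_event=True)
                )
            else:
                self._event_ledger(pid, "MH", seq, "condition", date,
                                   "MedDRA", code, "", False, date_text, False)
        if rng.random() < 0.15:
            seq += 1
            term = str(self.dict.free_text_conditions[
                int(rng.integers(2, len(self.dict.free_text_conditions)))
            ])
            date = enrollment - dt.timedelta(days=int(rng.integers(30, 2000)))
            date_text = self._degrade(date, rng)
            self.rows["MH"].append(
                {"USUBJID": pid, "MHSEQ": str(seq), "MHPTCD": "",
                 "MHDECOD": "", "MHTERM": term, "MHOCCUR": "Y"
                 if self.cfg.design == "prospective" else "",
                 "MHSTDTC": date_text}
            )
            self._event_ledger(pid, "MH", seq, "condition", date,
                               "free-text", "", term, False, date_text, False)

    def _vs(self, i: int, pid: str, enrollment: dt.date) -> None:
        rng = self.rng(i, "VS")
        n = int(rng.integers(1, 3))
        for seq in range(1, n + 1):
            test = str(self.dict.vs_tests[int(rng.integers(len(self.dict.vs_tests)))])
            date = self._rand_date(rng, enrollment, 700)
            self.rows["VS"].append(
                {"USUBJID": pid, "VSSEQ": str(seq), "VSPTCD": test,
                 "VSORRES": f"{rng.uniform(40.0, 180.0):.0f}",
                 "VSSTDTC": date.isoformat()}
            )
            self.ledger.append(
                LedgerRow(pid, "VS", seq, "other", date.isoformat(),
                          "VSTEST", test, self.dict.resolve("VSTEST", test))
            )

    def _xp(self, i: int, pid: str, enrollment: dt.date) -> None:
        rng = self.rng(i, "XP")
        date = self._rand_date(rng, enrollment, 200)
        self.rows["XP"].append(
            {"USUBJID": pid, "XPSEQ": "1", "XPPTCD": "MPAP",
             "XPORRES": f"{rng.uniform(25.0, 60.0):.0f}",
             "XPMETHOD": "THERMODILUTION", "XPSTDTC": date.isoformat()}
        )
        self.ledger.append(
            LedgerRow(pid, "XP", 1, "other", date.isoformat(),
                      "XPTEST", "MPAP", self.dict.resolve("XPTEST", "MPAP"))
        )
        grade = str(rng.choice(["I", "II", "III", "IV"]))
        self.rows["XP"].append(
            {"USUBJID": pid, "XPSEQ": "2", "XPPTCD": "WHOFC",
             "XPORRES": grade, "XPMETHOD": "", "XPSTDTC": date.isoformat()}
        )
        self.ledger.append(
            LedgerRow(pid, "XP", 2, "other", date.isoformat(),
                      "XPTEST", "WHOFC", self.dict.resolve("XPTEST", "WHOFC"))
        )

    def _dd(self, i: int, pid: str, death_date: dt.date) -> None:
        rng = self.rng(i, "DD")
        code, decod = self.dict.cause_of_death_codes[
            int(rng.integers(len(self.dict.cause_of_death_codes)))
        ]
        self.rows["DD"].append(
            {"USUBJID": pid, "DDSEQ": "1", "DDPTCD": code, "DDDECOD": decod,
             "DDSRC": "CRF", "DDSTDTC": self._degrade(death_date, rng)}
        )
        self.ledger.append(
            LedgerRow(pid, "DD", 1, "other", death_date.isoformat(),
                      "MedDRA", code, self.dict.resolve("MedDRA", code),
                      death=True)
        )
        if rng.random() < self.cfg.rate_conflicting_death_sources:
            shifted = death_date + dt.timedelta(days=int(rng.integers(-30, 31)))
            self.rows["DD"].append(
                {"USUBJID": pid, "DDSEQ": "2", "DDPTCD": code,
                 "DDDECOD": decod, "DDSRC": "SAFETY",
                 "DDSTDTC": self._degrade(shifted, rng)}
            )
            self.ledger.append(
                LedgerRow(pid, "DD", 2, "other", shifted.isoformat(),
                          "MedDRA", code, self.dict.resolve("MedDRA", code),
                          death=True)
            )


_COLUMNS = {
    "DM": ["USUBJID", "DMSPID", "SITEID", "BRTHDTC", "SEX", "RFSTDTC", "RFICDTC"],
    "AE": ["USUBJID", "AESEQ", "AEPTCD", "AEDECOD", "AETERM", "AESTDTC",
           "AEENDTC", "AESEV", "AEREL", "AEOUT"],
    "CM": ["USUBJID", "CMSEQ", "CMPTCD", "CMDECOD", "CMTERM", "CMSTDTC", "CMENDTC"],
    "EX": ["USUBJID", "EXSEQ", "EXPTCD", "EXDECOD", "EXSTDTC", "EXENDTC"],
    "LB": ["USUBJID", "LBSEQ", "LBPTCD", "LBORRES", "LBSTAT", "LBTPT", "LBSTDTC"],
    "MH": ["USUBJID", "MHSEQ", "MHPTCD", "MHDECOD", "MHTERM", "MHOCCUR", "MHSTDTC"],
    "VS": ["USUBJID", "VSSEQ", "VSPTCD", "VSORRES", "VSSTDTC"],
    "XP": ["USUBJID", "XPSEQ", "XPPTCD", "XPORRES", "XPMETHOD", "XPSTDTC"],
    "DS": ["USUBJID", "DSSEQ", "DSDECOD", "DSREAS", "DSSTDTC"],
    "DD": ["USUBJID", "DDSEQ", "DDPTCD", "DDDECOD", "DDSRC", "DDSTDTC"],
}


def generate(
    config: GeneratorConfig,
    store: Optional[VocabularyStore] = None,
) -> Tuple[StudyDataset, List[LedgerRow]]:
    """Generate one synthetic study and its ground-truth ledger."""
    from .sdtm import _parse_record  # reuse the exact reading path

    store = store or bundled_vocabulary()
    dictionary = MiniDictionary.from_store(store)
    builder = _StudyBuilder(config, dictionary)
    builder.build()

    mapping_config = config.mapping_config()
    study = StudyDataset(
        study_id=config.study_id,
        design=config.design,
        study_end_date=mapping_config.study_end_date,
        violator_ids=set(builder.violators),
    )
    for domain, columns in _COLUMNS.items():
        rows = builder.rows[domain]
        records = [
            _parse_record(domain, dict(row), idx + 1, mapping_config)
            for idx, row in enumerate(rows)
        ]
        study.tables[domain] = DomainTable(domain, records, list(columns))
    study.validate_referential_integrity()
    return study, builder.ledger


def write_fixture(
    config: GeneratorConfig,
    dir_path: Path | str,
    store: Optional[VocabularyStore] = None,
) -> Tuple[StudyDataset, List[LedgerRow]]:
    """Generate and write the study, violator list and ledger to a directory."""
    import csv

    study, ledger = generate(config, store)
    dir_path = Path(dir_path)
    write_study(study, dir_path)
    with (dir_path / "ledger.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "domain", "seq", "category", "true_date",
             "source_vocab", "source_code", "targets", "non_event",
             "unmappable", "undatable", "free_text_date", "death",
             "excluded_reason"]
        )
        for row in ledger:
            writer.writerow(
                [row.patient_id, row.domain, row.seq, row.category,
                 row.true_date, row.source_vocab, row.source_code,
                 "|".join(str(t) for t in row.targets), int(row.non_event),
                 int(row.unmappable), int(row.undatable),
                 int(row.free_text_date), int(row.death), row.excluded_reason]
            )
    return study, ledger


# ---------------------------------------------------------------------------
# the ledger oracle
# ---------------------------------------------------------------------------

@dataclass
class ExpectedQA:
    """Exact accounting the pipeline must reproduce on a generated study."""

    n_in_database: int
    n_violators: int
    n_mapping_excluded: int
    counts: Dict[str, QACounts]
    n_deaths: int

    @property
    def n_mapped(self) -> int:
        return self.n_in_database - self.n_violators - self.n_mapping_excluded


def expected_qa(ledger: List[LedgerRow]) -> ExpectedQA:
    """Compute, from ground truth alone, what the conversion must produce."""
    patient_rows = [r for r in ledger if r.category == "patient"]
    retained = {r.patient_id for r in patient_rows if not r.excluded_reason}
    n_violators = sum(
        1 for r in patient_rows if r.excluded_reason == "protocol_violator"
    )
    n_mapping_excluded = sum(
        1 for r in patient_rows
        if r.excluded_reason not in ("", "protocol_violator")
    )

    counts: Dict[str, QACounts] = {}
    for category in ("condition", "drug"):
        in_scope = [
            r for r in ledger
            if r.category == category and r.patient_id in retained
        ]
        mapped = [
            r for r in in_scope
            if not (r.non_event or r.unmappable or r.undatable)
        ]
        concept_ids = {t for r in mapped for t in r.targets}
        counts[category] = QACounts(
            category=category,
            n_unique_source_values=len(
                {(r.source_vocab, r.source_code) for r in in_scope}
            ),
            n_unique_concept_ids=len(concept_ids),
            n_unique_custom_concept_ids=sum(
                1 for c in concept_ids if c >= 2_000_000_000
            ),
            n_unique_source_records=len(in_scope),
            n_unique_cdm_records=sum(r.n_targets for r in mapped),
            n_unique_source_records_mapped=len(mapped),
            n_non_event=sum(1 for r in in_scope if r.non_event),
            n_unmapped=sum(
                1 for r in in_scope if r.unmappable and not r.non_event
            ),
            n_undatable=sum(
                1 for r in in_scope
                if r.undatable and not r.non_event and not r.unmappable
            ),
        )
    n_deaths = len(
        {r.patient_id for r in ledger if r.death and r.patient_id in retained}
    )
    return ExpectedQA(
        n_in_database=len(patient_rows),
        n_violators=n_violators,
        n_mapping_excluded=n_mapping_excluded,
        counts=counts,
        n_deaths=n_deaths,
    )
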