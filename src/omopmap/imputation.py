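"""Deterministic completion of partial and missing dates.

The CDM requires every event to carry a complete date, while registry
sources routinely record only a year, or a year and month, or nothing at
all.  Rather than excluding such records, dates are completed by four
deterministic strategies, each leaving a full audit trail:

i.   extraction of dates from free-text fields;
ii.  use of SDTM timepoint labels (via a configured label -> anchor table);
iii. imputation from the previous interval of taking the same drug;
iv.  comparison of the recorded year/month with pre-defined reference time
     points (death, drug initiation/end, last available information, last
     follow-up visit, end of study).

Generic completion fills a missing day with the first day of the month and
a missing day+month with 1 January of the recorded year.  Death dates have
their own algorithm: prefer the candidate with the fewest missing
components; break ties by source (death details from the CRF, then fatal
adverse events from the CRF, then the drug safety database); fall back to
the date of last available information; and never let a completed partial
death date precede the last available information.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .config import MappingConfig
from .dates import PartialDate

__all__ = [
    "ReferenceTimeline",
    "DeathCandidate",
    "DrugInterval",
    "ImputationResult",
    "impute_generic",
    "impute_drug_start",
    "impute_lab_date",
    "impute_death_date",
    "impute_by_timepoint",
    "UnresolvableDateError",
]

#: tie-break hierarchy for death-date sources, strongest first
DEATH_SOURCE_ORDER = ("crf_death_details", "crf_fatal_ae", "safety_db")


class UnresolvableDateError(ValueError):
    """No strategy can place this record on the calendar."""


@dataclass(frozen=True)
class DeathCandidate:
    source: str  # one of DEATH_SOURCE_ORDER
    date: PartialDate

    def __post_init__(self) -> None:
        if self.source not in DEATH_SOURCE_ORDER:
            raise ValueError(f"unknown death source {self.source!r}")

    @property
    def source_rank(self) -> int:
        return DEATH_SOURCE_ORDER.index(self.source)


@dataclass
class ReferenceTimeline:
    """Pre-defined reference time points for one patient."""

    patient_id: str
    drug_initiation: Optional[PartialDate] = None
    drug_end: Optional[PartialDate] = None
    last_available_info: Optional[dt.date] = None
    last_followup_visit: Optional[dt.date] = None
    study_end: Optional[dt.date] = None
    enrollment: Optional[dt.date] = None
    death_candidates: List[DeathCandidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (
            self.last_available_info is not None
            and self.study_end is not None
            and self.last_available_info > self.study_end
        ):
            raise ValueError(
                f"{self.patient_id}: last_available_info after study_end"
            )

    def anchor(self, name: str) -> Optional[dt.date]:
        value = getattr(self, name, None)
        if isinstance(value, PartialDate):
            return value.to_date() if value.is_complete else None
        return value


@dataclass(frozen=True)
class DrugInterval:
    patient_id: str
    drug_code: str
    start: PartialDate
    end: Optional[PartialDate]
    ordinal: int


@dataclass(frozen=True)
class ImputationResult:
    original: Optional[PartialDate]  # None when the date was fully missing
    imputed: dt.date
    strategy: Optional[str]  # None for an already-complete date (identity)
    notes: str = ""

    @property
    def was_imputed(self) -> bool:
        return self.strategy is not None


def impute_generic(partial: PartialDate) -> dt.date:
    """First-day-of-month / 1-January completion; identity when complete."""
    if partial.is_complete:
        return partial.to_date()
    if partial.month is not None:
        return dt.date(partial.year, partial.month, 1)
    return dt.date(partial.year, 1, 1)


def impute_drug_start(
    partial: PartialDate, prev_interval_end: Optional[dt.date]
) -> ImputationResult:
    """Complete a drug-initiation date, respecting the previous interval.

    The generic candidate is shifted to the day after the previous drug
    interval's end whenever it would otherwise start on or before that end.
    If the shifted date contradicts the recorded components (e.g. lands in
    a different month than the recorded month), the contradiction is
    flagged and the generic candidate retained.
    """
    if partial.is_complete:
        return ImputationResult(partial, partial.to_date(), None)
    candidate = impute_generic(partial)
    strategy = "reference_comparison"
    notes = "first-day completion"
    if prev_interval_end is not None and candidate <= prev_interval_end:
        shifted = prev_interval_end + dt.timedelta(days=1)
        if partial.agrees_with(shifted):
            return ImputationResult(
                partial, shifted, "prev_interval", "previous interval end + 1 day"
            )
        notes = (
            f"conflict: previous interval end + 1 day ({shifted.isoformat()}) "
            f"contradicts recorded parts {partial}; generic completion retained"
        )
    return ImputationResult(partial, candidate, strategy, notes)


def impute_lab_date(
    partial: Optional[PartialDate],
    timepoint: Optional[str],
    timeline: ReferenceTimeline,
) -> ImputationResult:
    """Complete a laboratory-test date from its timepoint context.

    * a drug-initiation timepoint whose recorded year/month agree with the
      drug initiation date takes that date;
    * a last-available-before-study-end timepoint takes the earlier of the
      drug end date and the study end date;
    * otherwise generic completion applies when a year exists; a record
      with no year and no applicable anchor is unresolvable and dropped
      with a logged reason.
    """
    if partial is not None and partial.is_complete:
        return ImputationResult(partial, partial.to_date(), None)

    label = (timepoint or "").strip().upper()
    if label in ("DRUG INITIATION", "TREATMENT START"):
        init = timeline.drug_initiation
        if init is not None and init.is_complete:
            init_date = init.to_date()
            if partial is None or partial.agrees_with(init_date):
                return ImputationResult(
                    partial, init_date, "timepoint", "drug initiation date"
                )
    if label in ("LAST AVAILABLE", "LAST AVAILABLE BEFORE STUDY END"):
        ends = [
            d
            for d in (
                timeline.drug_end.to_date()
                if timeline.drug_end is not None and timeline.drug_end.is_complete
                else None,
                timeline.study_end,
            )
            if d is not None
        ]
        if ends:
            return ImputationResult(
                partial, min(ends), "timepoint",
                "earlier of drug end date and study end date",
            )
    if partial is not None:
        return ImputationResult(
            partial, impute_generic(partial), "reference_comparison",
            "generic completion",
        )
    raise UnresolvableDateError(
        f"{timeline.patient_id}: no year recorded and timepoint "
        f"{timepoint!r} resolves no anchor"
    )


def _select_death_candidate(
    candidates: Sequence[DeathCandidate],
) -> Optional[DeathCandidate]:
    if not candidates:
        return None
    # fewest missing components first; ties broken by the source hierarchy
    return min(candidates, key=lambda c: (c.date.n_missing_parts, c.source_rank))


def impute_death_date(
    candidates: Sequence[DeathCandidate],
    last_available_info: Optional[dt.date],
) -> ImputationResult:
    """Place a recorded death on the calendar.

    Selection prefers the candidate with the fewest missing date parts,
    breaking ties with the source hierarchy (CRF death details, then CRF
    fatal adverse events, then the drug safety database).  With no usable
    candidate the date of last available information stands in.  A partial
    candidate is completed generically and floored at the date of last
    available information.  The result is invariant under permutation of
    the candidate list.
    """
    chosen = _select_death_candidate(candidates)
    if chosen is None:
        if last_available_info is None:
            raise UnresolvableDateError(
                "death recorded but no dated source and no last available information"
            )
        return ImputationResult(
            None, last_available_info, "death_hierarchy",
            "no dated candidate; date of last available information",
        )
    partial = chosen.date
    if partial.is_complete:
        return ImputationResult(
            partial, partial.to_date(),
            "death_hierarchy" if len(candidates) > 1 else None,
            f"complete date from {chosen.source}",
        )
    completed = impute_generic(partial)
    if last_available_info is not None and completed < last_available_info:
        return ImputationResult(
            partial, last_available_info, "death_hierarchy",
            f"partial {partial} from {chosen.source} completed to "
            f"{completed.isoformat()}, floored at last available information",
        )
    return ImputationResult(
        partial, completed, "death_hierarchy",
        f"partial {partial} from {chosen.source}, generic completion",
    )


def impute_by_timepoint(
    timepoint: str, timeline: ReferenceTimeline, config: MappingConfig
) -> Optional[dt.date]:
    """Resolve a timepoint label to a date via the configured anchor table.

    Returns the anchor date plus the configured day offset, or None when
    the label is unmapped or the anchor is absent from the timeline.
    """
    rule = config.timepoint_rule(timepoint)
    if rule is None:
        return None
    anchor = timeline.anchor(rule.anchor)
    if anchor is None:
        return None
    return anchor + dt.timedelta(days=rule.offset_days)


def audit_row(
    patient_id: str, domain: str, seq: int, result: ImputationResult
) -> Tuple[str, str, int, str, str, str, str]:
    """One delimited audit-log row per applied imputation."""
    return (
        patient_id,
        domain,
        seq,
        result.original.isoformat() if result.original is not None else "",
        result.imputed.isoformat(),
        result.strategy or "",
        result.notes,
    )
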