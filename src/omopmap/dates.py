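"""Partial calendar dates as they occur in SDTM registry exports.

SDTM stores dates as ISO-8601 prefixes: a record may carry a full date
("2015-06-11"), only year and month ("2015-06"), or only a year ("2015").
:class:`PartialDate` is the central object of the downstream imputation
machinery: it keeps exactly the components that were recorded and nothing
else, so that every completion of a date is an explicit, auditable act.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PartialDate",
    "PartialDateError",
    "parse_partial_date",
    "extract_date_from_text",
]


class PartialDateError(ValueError):
    """A string did not conform to the ISO-8601 prefix grammar.

    Carries the verbatim offending text in :attr:`text` so callers can
    preserve it untouched in the source record.
    """

    def __init__(self, text: str, reason: str = "not an ISO-8601 date prefix"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date with optional month and day.

    Invariants enforced on construction:

    * a day requires a month; a month requires a year (the year is always
      required);
    * a complete (year, month, day) triple must be a valid calendar date;
    * a (year, month) pair must have ``1 <= month <= 12``.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day present without month")
        if not (1 <= self.year <= 9999):
            raise ValueError(f"year out of range: {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegates calendar validity (leap years, month lengths)
            dt.date(self.year, self.month, self.day)

    # -- classification ---------------------------------------------------

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    @property
    def n_missing_parts(self) -> int:
        """Number of missing components (0, 1, or 2)."""
        return (self.month is None) + (self.day is None)

    # -- conversions ------------------------------------------------------

    def to_date(self) -> dt.date:
        """Return the exact :class:`datetime.date`; only valid when complete."""
        if not self.is_complete:
            raise ValueError(f"partial date {self} is not complete")
        return dt.date(self.year, self.month, self.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()

    @classmethod
    def from_date(cls, d: dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def agrees_with(self, complete: dt.date) -> bool:
        """True when every recorded component equals that of ``complete``."""
        if self.year != complete.year:
            return False
        if self.month is not None and self.month != complete.month:
            return False
        if self.day is not None and self.day != complete.day:
            return False
        return True


_ISO_PREFIX = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")


def parse_partial_date(text: str) -> PartialDate:
    """Parse an ISO-8601 date prefix ("YYYY", "YYYY-MM", or "YYYY-MM-DD").

    Anything else — free text, slashed dates, out-of-range components —
    raises :class:`PartialDateError` carrying the verbatim input.
    Free-text dates are the business of :func:`extract_date_from_text`.
    """
    m = _ISO_PREFIX.match(text.strip())
    if m is None:
        raise PartialDateError(text)
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    try:
        return PartialDate(year, month, day)
    except ValueError as exc:
        raise PartialDateError(text, str(exc)) from exc


# Free-text date dialects, ordered most-specific first so that the leftmost
# match at a position prefers the longest interpretation ("2015-06-11" is a
# full date, not the year 2015).  The dialect list is fixed and documented;
# anything outside it is deliberately not a date.
_MONTHS = {
    name.lower(): i
    for i, names in enumerate(
        [
            ("jan", "january"), ("feb", "february"), ("mar", "march"),
            ("apr", "april"), ("may",), ("jun", "june"), ("jul", "july"),
            ("aug", "august"), ("sep", "sept", "september"),
            ("oct", "october"), ("nov", "november"), ("dec", "december"),
        ],
        start=1,
    )
    for name in names
}
_MON = r"(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|jul(?:y)?|aug(?:ust)?|sep(?:t(?:ember)?)?|oct(?:ober)?|nov(?:ember)?|dec(?:ember)?)"

_FREE_TEXT_DATE = re.compile(
    r"(?<![\d/-])(?:"
    r"(?P<iso_full>\d{4}-\d{2}-\d{2})"
    r"|(?P<iso_ym>\d{4}-\d{2})"
    r"|(?P<slashed>\d{1,2}/\d{1,2}/\d{4})"
    r"|(?P<dmy>\d{1,2}\s+" + _MON + r"\s+\d{4})"
    r"|(?P<my>" + _MON + r"\s+\d{4})"
    r"|(?P<y>\d{4})"
    r")(?![\d/-])",
    re.IGNORECASE,
)


def extract_date_from_text(text: str) -> Optional[PartialDate]:
    """Scan free text for a date and return the first full match, or None.

    Recognized dialects, in order of preference at a given position:
    ISO prefixes ("2015-06-11", "2015-06", "2015"), US-style "MM/DD/YYYY",
    "DD Mon YYYY", and "Mon YYYY" (English month names or abbreviations).
    A candidate that matches a dialect but is not a valid calendar date is
    skipped and scanning continues.
    """
    for m in _FREE_TEXT_DATE.finditer(text):
        try:
            if m.group("iso_full") or m.group("iso_ym") or m.group("y"):
                return parse_partial_date(m.group(0))
            if m.group("slashed"):
                mm, dd, yyyy = m.group(0).split("/")
                return PartialDate(int(yyyy), int(mm), int(dd))
            if m.group("dmy"):
                dd, mon, yyyy = m.group(0).split()
                return PartialDate(int(yyyy), _MONTHS[mon.lower()], int(dd))
            if m.group("my"):
                mon, yyyy = m.group(0).split()
                return PartialDate(int(yyyy), _MONTHS[mon.lower()])
        except (ValueError, PartialDateError):
            continue
    return None
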