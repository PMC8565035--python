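"""Mapping configuration: the structured knobs of a registry conversion.

Everything a conversion run needs beyond the data itself lives here: where
the domain files and vocabulary tables are, the study design, the study end
date, the timepoint-to-anchor table used by date imputation, which of the
alternative disposition concepts to emit, and the (by default empty) list
of source variables dropped as irrelevant to analyses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .dates import PartialDate, parse_partial_date

__all__ = ["TimepointRule", "MappingConfig", "load_config"]

#: default source-vocabulary per SDTM domain for coded terms
DEFAULT_DOMAIN_VOCABULARY: Dict[str, str] = {
    "AE": "MedDRA",
    "MH": "MedDRA",
    "DD": "MedDRA",
    "CM": "WHODrug",
    "EX": "WHODrug",
    "LB": "LBTEST",
    "VS": "VSTEST",
    "XP": "XPTEST",
}


@dataclass(frozen=True)
class TimepointRule:
    """Maps one SDTM timepoint label to a reference-timeline anchor.

    ``anchor`` names a field of the reference timeline (``drug_initiation``,
    ``drug_end``, ``last_available_info``, ``last_followup_visit``,
    ``study_end``, ``enrollment``); ``offset_days`` shifts the anchor date.
    """

    label: str
    anchor: str
    offset_days: int = 0


DEFAULT_TIMEPOINT_RULES: List[TimepointRule] = [
    TimepointRule("DRUG INITIATION", "drug_initiation"),
    TimepointRule("LAST AVAILABLE", "last_available_info"),
    TimepointRule("BEFORE DISCONTINUATION", "last_available_info"),
    TimepointRule("WITHIN 3 MONTHS OF BASELINE", "enrollment"),
    TimepointRule("BASELINE", "enrollment"),
]


@dataclass
class MappingConfig:
    """Configuration of one SDTM-to-CDM conversion run."""

    input_dir: Optional[Path] = None
    vocab_dir: Optional[Path] = None
    output_dir: Optional[Path] = None
    study_id: str = "STUDY"
    design: str = "prospective"  # or "retrospective"
    study_end_date: Optional[PartialDate] = None
    domain_vocabulary: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_VOCABULARY)
    )
    #: per-domain variable-name overrides, e.g. {"AE": {"start": "AESDTC"}}
    variable_overrides: Dict[str, Dict[str, str]] = field(default_factory=dict)
    timepoint_rules: List[TimepointRule] = field(
        default_factory=lambda: list(DEFAULT_TIMEPOINT_RULES)
    )
    #: which of the alternative disposition concepts to emit per category
    disposition_concepts: Dict[str, int] = field(
        default_factory=lambda: {
            "enrollment": 44807982,   # Participant in research study
            "consent": 44811375,      # Consent given to participate ...
            "completion": 44810922,   # Participation in research study completed
            "withdrawal": 44810920,   # Withdrawn from research study
        }
    )
    #: source variable names dropped as irrelevant to analyses (empty default)
    drop_variables: List[str] = field(default_factory=list)
    seed: int = 0

    def variable(self, domain: str, role: str, default: str) -> str:
        """Resolve a variable name for (domain, role), honouring overrides."""
        return self.variable_overrides.get(domain, {}).get(role, default)

    def study_end(self) -> Optional[dt.date]:
        if self.study_end_date is None:
            return None
        if self.study_end_date.is_complete:
            return self.study_end_date.to_date()
        return None

    def timepoint_rule(self, label: str) -> Optional[TimepointRule]:
        wanted = label.strip().upper()
        for rule in self.timepoint_rules:
            if rule.label.upper() == wanted:
                return rule
        return None


def load_config(path: Path | str) -> MappingConfig:
    """Load a YAML mapping configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = MappingConfig()
    for key in ("input_dir", "vocab_dir", "output_dir"):
        if key in raw and raw[key] is not None:
            setattr(cfg, key, Path(raw[key]))
    for key in ("study_id", "design", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if raw.get("study_end_date"):
        cfg.study_end_date = parse_partial_date(str(raw["study_end_date"]))
    if "domain_vocabulary" in raw:
        cfg.domain_vocabulary.update(raw["domain_vocabulary"])
    if "variable_overrides" in raw:
        cfg.variable_overrides = {
            str(k): dict(v) for k, v in raw["variable_overrides"].items()
        }
    if "timepoint_rules" in raw:
        cfg.timepoint_rules = [
            TimepointRule(r["label"], r["anchor"], int(r.get("offset_days", 0)))
            for r in raw["timepoint_rules"]
        ]
    if "disposition_concepts" in raw:
        cfg.disposition_concepts.update(
            {k: int(v) for k, v in raw["disposition_concepts"].items()}
        )
    if "drop_variables" in raw:
        cfg.drop_variables = [str(v) for v in raw["drop_variables"]]
    return cfg
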