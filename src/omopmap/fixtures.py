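"""Bundled miniature OMOP vocabulary for self-contained conversion runs.

Full OMOP vocabularies are distributed through Athena and are far too large
to ship; this module builds a ~80-concept store that contains every
standard concept the worked examples and the disposition/outcome/method
patterns use (those concept ids are the real OMOP ids), together with a
small *synthetic* SNOMED-like pulmonary-hypertension hierarchy, MedDRA-like
classification concepts, WHODrug-like drug codes, and the curated
crosswalk that resolves them.  Synthetic members carry ids in documented
private ranges (36xx/37xx/39xx/42xx millions) and stand in for vocabulary
content that cannot be redistributed; custom concepts proper (disease
subgroups, WHO functional class) are registered through the normal
custom-concept path and land in the >= 2,000,000,000 range.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .vocabulary import (
    Concept,
    ConceptRelationship,
    CrosswalkEntry,
    VocabularyStore,
)

__all__ = [
    "bundled_vocabulary",
    "TABLE_CONCEPT_IDS",
    "SEVERITY_VALUE_IDS",
    "OUTCOME_VALUE_IDS",
    "CAUSALITY_VALUE_IDS",
    "GENDER_CONCEPT_IDS",
    "CONDITION_SEVERITY_ID",
    "OUTCOME_CATEGORY_ID",
    "MEASUREMENT_METHOD_REL_ID",
    "THERMODILUTION_ID",
    "MPAP_ID",
]

# Standard concepts printed in the worked examples (real OMOP ids)
CONDITION_SEVERITY_ID = 4022772       # Condition severity
MODERATE_ID = 4285732                 # Moderate
MPAP_ID = 3028074                     # Pulmonary artery Mean blood pressure
THERMODILUTION_ID = 4122989           # Thermodilution technique
MEASUREMENT_METHOD_REL_ID = 4152892   # Measurement method
OUTCOME_CATEGORY_ID = 4231813         # Adverse incident outcome categories

#: CDM-table metadata concepts used as FACT_RELATIONSHIP domain ids.  The
#: observation and measurement table ids are the standard ones; the rest of
#: the tables get local metadata concepts in the custom range.
TABLE_CONCEPT_IDS: Dict[str, int] = {
    "observation": 1147304,
    "measurement": 1147330,
    "condition_occurrence": 2_000_000_901,
    "drug_exposure": 2_000_000_902,
    "procedure_occurrence": 2_000_000_903,
    "visit_occurrence": 2_000_000_904,
}

GENDER_CONCEPT_IDS: Dict[str, int] = {"M": 8507, "F": 8532}

SEVERITY_VALUE_IDS: Dict[str, int] = {
    "MILD": 4171373,
    "MODERATE": MODERATE_ID,
    "SEVERE": 4171374,
}

CAUSALITY_VALUE_IDS: Dict[str, int] = {
    "N": 45878245,        # No
    "UNLIKELY": 45877241, # Unlikely
    "Y": 45877994,        # Yes
    "POSSIBLE": 4162850,  # Possible
}

OUTCOME_VALUE_IDS: Dict[str, int] = {
    "RECOVERED": 4165327,
    "RECOVERING": 4165328,
    "NOT RECOVERED": 4165329,
}

_STANDARD_CONCEPTS: Tuple[Tuple[int, str, str], ...] = (
    # (concept_id, name, domain)
    (4030518, "Renal impairment", "Condition"),
    (CONDITION_SEVERITY_ID, "Condition severity", "Observation"),
    (MODERATE_ID, "Moderate", "Meas Value"),
    (MPAP_ID, "Pulmonary artery Mean blood pressure", "Measurement"),
    (THERMODILUTION_ID, "Thermodilution technique", "Observation"),
    (MEASUREMENT_METHOD_REL_ID, "Measurement method", "Metadata"),
    (1147304, "Observation table", "Metadata"),
    (1147330, "Measurement table", "Metadata"),
    (4249456, "Complication of catheter", "Condition"),
    (4183956, "Skin discharge", "Condition"),
    (44807982, "Participant in research study", "Observation"),
    (4090379, "Patient entered into trial", "Observation"),
    (44811375, "Consent given to participate in research study", "Observation"),
    (4163733, "Patient consented to clinical trial", "Observation"),
    (44810922, "Participation in research study completed", "Observation"),
    (44810920, "Withdrawn from research study", "Observation"),
    (40482840, "Completion of clinical trial", "Observation"),
    (4087907, "Patient withdrawn from trial", "Observation"),
    (OUTCOME_CATEGORY_ID, "Adverse incident outcome categories", "Observation"),
    (4322024, "Pulmonary hypertension", "Condition"),
    (45878245, "No", "Meas Value"),
    (45877241, "Unlikely", "Meas Value"),
    (45877994, "Yes", "Meas Value"),
    (4162850, "Possible", "Meas Value"),
    (45885208, "Other reason", "Meas Value"),
    (8507, "Male", "Gender"),
    (8532, "Female", "Gender"),
    (8876, "millimeter mercury column", "Unit"),
    (4171373, "Mild", "Meas Value"),
    (4171374, "Severe", "Meas Value"),
    (4165327, "Recovered", "Meas Value"),
    (4165328, "Recovering", "Meas Value"),
    (4165329, "Not recovered", "Meas Value"),
)

# Synthetic SNOMED-like condition concepts (37xx million private range)
_SYN_CONDITIONS: Tuple[Tuple[int, str], ...] = (
    (37000001, "Pulmonary arterial hypertension"),
    (37000002, "Chronic thromboembolic pulmonary hypertension"),
    (37000003, "Connective tissue disease overlap syndrome"),
    (37000004, "History of surgically corrected congenital heart defect"),
    (37000005, "Peripheral edema"),
    (37000006, "Dyspnea"),
    (37000007, "Anemia"),
    (37000008, "Syncope"),
    (37000009, "Right heart failure"),
    (37000010, "Systemic hypertension"),
    (37000011, "Diabetes mellitus"),
    (37000012, "Atrial fibrillation"),
    (37000013, "Headache"),
    (37000014, "Respiratory tract infection"),
)

# MedDRA-like classification concepts (36xx million private range); the
# concept_code is the MedDRA-style numeric source code.
_MEDDRA: Tuple[Tuple[int, str, str, Tuple[int, ...]], ...] = (
    # (concept_id, code, name, crosswalk targets)
    (36000001, "10057688", "Catheter site discharge", (4249456, 4183956)),
    (36000002, "10038428", "Renal impairment", (4030518,)),
    (36000003, "10064911", "Pulmonary arterial hypertension", (37000001,)),
    (36000004, "10051297", "Peripheral edema", (37000005,)),
    (36000005, "10013968", "Dyspnoea", (37000006,)),
    (36000006, "10002034", "Anaemia", (37000007,)),
    (36000007, "10042772", "Syncope", (37000008,)),
    (36000008, "10019279", "Right heart failure", (37000009,)),
    (36000009, "10020772", "Hypertension", (37000010,)),
    (36000010, "10012601", "Diabetes mellitus", (37000011,)),
    (36000011, "10003658", "Atrial fibrillation", (37000012,)),
    (36000012, "10019211", "Headache", (37000013,)),
    (36000013, "10062352", "Respiratory tract infection", (37000014,)),
)

# Drug concepts, RxNorm-like (42xx million private range), and the
# WHODrug-like codes that resolve to them.
_DRUGS: Tuple[Tuple[int, str, str], ...] = (
    # (concept_id, WHODrug-like code, name)
    (42000001, "WD000101", "macitentan"),
    (42000002, "WD000102", "selexipag"),
    (42000003, "WD000201", "sildenafil"),
    (42000004, "WD000202", "tadalafil"),
    (42000005, "WD000301", "furosemide"),
    (42000006, "WD000302", "warfarin"),
    (42000007, "WD000303", "digoxin"),
)

# Measurement concepts for laboratory / vitals / haemodynamic tests
# (39xx million private range except the printed mPAP id).
_TESTS: Tuple[Tuple[int, str, str, str], ...] = (
    # (concept_id, source vocab, source code, name)
    (39000001, "LBTEST", "NTPROBNP", "NT-proBNP serum level"),
    (39000002, "LBTEST", "CREAT", "Serum creatinine"),
    (39000003, "LBTEST", "HGB", "Hemoglobin"),
    (39000004, "LBTEST", "ALT", "Alanine aminotransferase"),
    (39000011, "VSTEST", "SYSBP", "Systolic blood pressure"),
    (39000012, "VSTEST", "DIABP", "Diastolic blood pressure"),
    (39000013, "VSTEST", "HR", "Heart rate"),
    (39000014, "VSTEST", "WEIGHT", "Body weight"),
)

# Free-text entries the curated crosswalk resolves (medication and
# condition wording seen verbatim in source tables).
_FREE_TEXT_DRUGS: Tuple[Tuple[str, int], ...] = (
    ("macitentan 10 mg", 42000001),
    ("selexipag tablets", 42000002),
    ("lasix", 42000005),
)
_FREE_TEXT_CONDITIONS: Tuple[Tuple[str, int], ...] = (
    ("swelling of both ankles", 37000005),
    ("short of breath on exertion", 37000006),
)


def bundled_vocabulary() -> VocabularyStore:
    """Build the self-contained vocabulary store used by the bundled runs.

    Registration order is fixed, so the custom-concept ids it allocates
    are deterministic.
    """
    store = VocabularyStore()
    for cid, name, domain in _STANDARD_CONCEPTS:
        vocab = {
            "Gender": "Gender",
            "Unit": "UCUM",
            "Metadata": "CDM",
            "Meas Value": "SNOMED",
        }.get(domain, "SNOMED")
        store.add_concept(Concept(cid, name, domain, vocab, "standard"))
    for cid, name in _SYN_CONDITIONS:
        store.add_concept(Concept(cid, name, "Condition", "SNOMED", "standard"))
    for cid, code, name, _ in _MEDDRA:
        store.add_concept(
            Concept(cid, name, "Condition", "MedDRA", "classification", False, code)
        )
    for cid, code, name in _DRUGS:
        store.add_concept(Concept(cid, name, "Drug", "RxNorm", "standard"))
        store.add_concept(
            Concept(
                cid + 1_000_000, name + " (WHODrug)", "Drug", "WHODrug",
                "non_standard", False, code,
            )
        )
        store.add_relationship(
            ConceptRelationship(cid + 1_000_000, cid, "Maps to")
        )
    for cid, vocab, code, name in _TESTS:
        store.add_concept(Concept(cid, name, "Measurement", vocab, "standard", False, code))

    # synthetic PH hierarchy: PAH and CTEPH under pulmonary hypertension
    store.add_relationship(ConceptRelationship(37000001, 4322024, "Is a"))
    store.add_relationship(ConceptRelationship(37000002, 4322024, "Is a"))

    # custom range: table metadata concepts for FACT_RELATIONSHIP domains
    for table, cid in TABLE_CONCEPT_IDS.items():
        if cid >= 2_000_000_000:
            store.add_concept(
                Concept(cid, f"{table} table (local)", "Metadata", "Custom", "standard", True)
            )

    # custom concepts proper — disease subgroups and WHO functional class
    dtx = store.register_custom_concept(
        "Drug- and toxin-induced pulmonary arterial hypertension",
        "Condition", [37000001],
    )
    grp5 = store.register_custom_concept(
        "Pulmonary hypertension with unclear or multifactorial mechanisms",
        "Condition", [4322024],
    )
    whofc = store.register_custom_concept("WHO functional class", "Observation", [])
    fc = {
        n: store.register_custom_concept(f"WHO functional class {n}", "Meas Value", [])
        for n in ("I", "II", "III", "IV")
    }
    rel_entity = store.register_custom_concept("Relationship to <entity>", "Observation", [])
    store.register_custom_concept("Has characteristic", "Metadata", [])

    # curated crosswalk: MedDRA codes, WHODrug codes, tests, free text
    for cid, code, name, targets in _MEDDRA:
        store.add_crosswalk_entry(
            CrosswalkEntry("MedDRA", code, targets, "manual")
        )
    for cid, code, name in _DRUGS:
        store.add_crosswalk_entry(
            CrosswalkEntry("WHODrug", code, (cid,), "automated")
        )
    for cid, vocab, code, name in _TESTS:
        store.add_crosswalk_entry(CrosswalkEntry(vocab, code, (cid,), "manual"))
    store.add_crosswalk_entry(
        CrosswalkEntry("XPTEST", "MPAP", (MPAP_ID,), "manual")
    )
    store.add_crosswalk_entry(
        CrosswalkEntry("XPTEST", "WHOFC", (whofc,), "custom")
    )
    for text, cid in _FREE_TEXT_DRUGS + _FREE_TEXT_CONDITIONS:
        store.add_crosswalk_entry(
            CrosswalkEntry("free-text", text, (cid,), "manual")
        )
    store.add_crosswalk_entry(
        CrosswalkEntry("free-text", "drug- and toxin-induced PAH", (dtx,), "custom")
    )
    store.add_crosswalk_entry(
        CrosswalkEntry(
            "free-text", "PH with unclear and/or multifactorial mechanisms",
            (grp5,), "custom",
        )
    )
    for n, cid in fc.items():
        store.add_crosswalk_entry(
            CrosswalkEntry("WHOFC", n, (cid,), "custom")
        )
    store.add_crosswalk_entry(
        CrosswalkEntry("DSREAS", "OTHER", (45885208,), "manual")
    )

    store.build_ancestor_closure()
    return store


def custom_concept_ids(store: VocabularyStore) -> Dict[str, int]:
    """Name -> id for the custom concepts of a store (diagnostics)."""
    return {
        c.name: c.concept_id for c in store.concepts.values() if c.is_custom
    }
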