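# omopmap

Harmonization of SDTM-style clinical registry data to the OMOP Common Data
Model (CDM) v5.3.1, with deterministic partial-date imputation,
custom-vocabulary extension, and a full mapping quality-assessment
accounting.

## The problem

Disease registries — here, registries of patients with pulmonary
hypertension (PH) and its rare subgroups such as pulmonary arterial
hypertension (PAH) — typically store their data in CDISC's Study Data
Tabulation Model (SDTM): one table per two-letter domain (DM demographics,
AE adverse events, CM concomitant medications, EX drug exposure, LB
laboratory tests, MH medical history, VS vital signs, DD death details, DS
disposition, plus custom domains such as XP for haemodynamic assessments).
SDTM is flexible: free-text fields, optional dates, tick-box checklists
that record *non*-occurrence as well as occurrence. The OMOP CDM is the
opposite: a fixed, patient-centric schema in which every clinical event
carries a standard concept id and a complete calendar date, which makes it
the lingua franca of federated observational research networks — exactly
what rare-disease research needs, and exactly what flexible registry data
does not provide out of the box.

`omopmap` implements the conversion between the two, for analysts
harmonizing registry studies into a common format:

* **Sample selection** — protocol violators, patients with essential data
  completely missing (birth year; treatment start *and* end dates), and
  duplicate patient records are excluded, with two-row patient accounting
  (violators vs. mapping exclusions) and a per-patient exclusion log.
* **Partial-date imputation** — SDTM dates are ISO-8601 prefixes
  (`2015`, `2015-06`, `2015-06-11`). Four deterministic strategies
  complete them: extraction from free text; timepoint labels resolved
  through a configurable anchor table; the previous drug interval
  (start ≤ previous end ⇒ previous end + 1 day); and comparison with
  reference time points (first-day-of-month / 1-January completion,
  drug initiation and end, study end, date of last available
  information). Death dates follow their own algorithm: fewest missing
  components first, ties broken by source (CRF death details ≻ CRF fatal
  adverse events ≻ safety database), floored at the date of last
  available information. Every completion is written to an audit log.
* **Vocabulary resolution** — MedDRA-coded conditions and WHODrug-coded
  medications resolve through a curated crosswalk to standard (SNOMED /
  RxNorm / LOINC-like) concepts; one source code may fan out to several
  targets. Content the standard vocabularies lack (PAH subgroups, WHO
  functional class) is covered by *custom concepts* (ids ≥ 2,000,000,000)
  integrated into the hierarchy via `Is a` relationships and a rebuilt
  `CONCEPT_ANCESTOR` transitive closure (min/max level separations), or
  by combinations of standard concepts emitted as linked rows.
* **Domain routing and linking** — each resolved concept's domain decides
  its CDM table (Condition → `CONDITION_OCCURRENCE`, etc.). Non-occurrence
  records (`--OCCUR` in {N, U}, `--STAT` = NOT DONE) are not mapped, per
  CDM convention, and are counted per reason. Event characteristics —
  severity, causality, outcome, method of measurement — become
  observation rows tied to their event by mirrored `FACT_RELATIONSHIP`
  pairs.
* **Quality assessment** — patient-level exclusion accounting
  (`n_mapped = n_in_database − n_violators − n_excluded`), source-value
  consolidation (redundancy) rates, record-level mapping rates with and
  without non-event records, and an SDTM-vs-CDM demographic consistency
  check (mean/SD age at enrollment, gender distribution). On synthetic
  data the accounting closes exactly against the generator's ground-truth
  ledger: mapped + non-event + unmapped + undatable = total, no silent
  loss.

Because real registry databases are proprietary, the package ships a
deterministic synthetic-registry generator (`omopmap.synthetic`) that
reproduces their structural pathologies — partial and free-text dates,
non-occurrence checklists, duplicate patients, protocol violators,
conflicting death sources, unmappable codes — together with a
ground-truth ledger from which the expected result of every pipeline
stage is computed exactly.

## Worked example

```sh
omopmap generate --n-patients 200 --seed 11 --output demo/study
omopmap map --input demo/study --output demo/cdm
omopmap qa --cdm demo/cdm --source demo/study --report demo/qa.json
```

prints

```
generated 207 patients, 4202 records, 4202 ledger rows -> demo/study
using bundled vocabulary
mapped 189/207 patients (91.3%); 4600 event rows, 2670 fact-relationship rows
QA report written to demo/qa.json
  condition: 1613 source records -> 1048 CDM records (16 concepts, 2 custom)
  drug: 688 source records -> 675 CDM records (7 concepts, 0 custom)
```

207 patients are in the database (200 plus 7 duplicate entries); 5
violators and 13 mapping exclusions (duplicates, missing birth year,
missing treatment dates) leave 189 mapped (91.3%). The 1613 condition
source records shrink to 1048 CDM rows mostly because checklist items
ticked "did not occur" are not mapped; two custom concepts appear because
some free-text medical-history entries name PAH subgroups the standard
vocabulary lacks. `demo/qa.json` carries the full accounting, e.g. the
demographic consistency check (mean age 57.57 on both sides, no flags).

The library surface mirrors the CLI: `read_study`, `run_mapping`,
`compute_qa_report`, `bundled_vocabulary`, and
`synthetic.generate`/`expected_qa` for oracle-backed testing. Vocabulary
maintenance (`omopmap vocab-register`) and QA-report comparison across
data refreshes (`omopmap diff-qa`) round out the workflow.

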