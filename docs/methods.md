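# Methods

## Scope and shape of the conversion

The package converts one registry study at a time from SDTM-style domain
tables (comma-delimited UTF-8, RFC-4180 quoting, one file per domain) to
OMOP CDM v5.3.1 event tables. The conversion is a pure function of
(input files, vocabulary, configuration): stages run in a fixed order,
all iteration orders are explicit (patients sorted by id, records by
sequence number, domains in a fixed list), and surrogate keys
(`person_id`, per-table event ids) are assigned sequentially in that
order. Two runs on the same inputs produce byte-identical outputs; this
is load-bearing, because the quality-assessment accounting is checked
against an independently computed expectation down to exact counts.

Reading is strictly non-destructive. Every cell of every source row is
kept verbatim in the record's `values` map; typed fields (partial dates,
occurrence flags, coded terms) are parsed views. A date cell that fails
the ISO-8601 prefix grammar is preserved verbatim and flagged — the
free-text extraction strategy may recover it later, but nothing is ever
silently normalized at read time. `write_study(read_study(d))`
reproduces conforming inputs cell-for-cell.

## Partial dates and imputation

A `PartialDate` holds exactly the recorded components: year; year+month;
or a full date. Invariants (day ⇒ month ⇒ year; calendar validity) are
enforced at construction, so downstream code never revalidates.

Completion strategies, in the order the pipeline tries them:

1. **Free-text extraction.** When a date cell failed to parse, the text
   is scanned against a fixed dialect list — ISO prefixes, `MM/DD/YYYY`,
   `DD Mon YYYY`, `Mon YYYY`, bare `YYYY` — longest interpretation first
   at each position; the first full match wins and invalid calendar
   candidates (e.g. 30 February) are skipped. The dialect list is
   deliberately closed: anything else is *not* a date, because guessing
   costs auditability.
2. **Timepoint labels.** Registry label vocabularies are not
   standardized, so the label → anchor mapping is configuration, not
   code: each rule names a reference-timeline field (drug initiation or
   end, last available information, last follow-up visit, study end,
   enrollment) and a day offset (default 0). Unmapped labels resolve to
   nothing rather than to a guess.
3. **Previous drug interval.** A partial drug start is first completed
   generically; if that lands on or before the end of the previous
   interval of the same drug, it moves to that end plus one day. If the
   shift would contradict a recorded component (e.g. land in a different
   month than the recorded month), the contradiction is flagged in the
   audit note and the generic completion is kept — recorded data beats
   derived constraints.
4. **Reference comparison / generic completion.** Missing day → first of
   the month; missing day and month → 1 January. Laboratory dates get two
   specializations: a drug-initiation timepoint whose recorded components
   agree with the (complete) drug initiation date takes that date; a
   last-available timepoint takes the earlier of drug end and study end.

Death dates: candidates are gathered from CRF death-details rows, fatal
adverse events, and safety-database rows. Selection takes the candidate
with the fewest missing components; ties break by source hierarchy (CRF
death details, then fatal AEs, then safety DB). The published rule states
only the tie case; preferring the more complete candidate in the strict
case is this package's inference, consistent with the rule's evident
intent of using the most complete date. A selected partial candidate is
completed generically and then floored at the date of last available
information; with no usable candidate, the date of last available
information stands in. Selection is a pure `min` over a total order, so
the result is invariant under permutation of the candidate list (property
tested). Single-source selection is used rather than assembling a
composite date from components of different sources; the alternative
reading exists but mixes provenance within one date.

The *date of last available information* is derived as the latest
complete recorded date of the patient outside the death-details domain,
capped at the study end date. Records with no year and no applicable
anchor are undatable: dropped with a logged reason and counted in the QA
accounting (a CDM event must have a date).

Every applied completion writes one audit row (patient, domain, sequence,
original, imputed, strategy, note). Completing an already-complete date
is the identity and records nothing.

## Vocabulary model

The store mirrors the OMOP vocabulary tables: concepts (standard,
classification, non-standard, custom), relationships (`Maps to`,
`Is a`, custom-labelled), the `CONCEPT_ANCESTOR` closure, and the curated
crosswalk. Resolution order is: exact crosswalk entry (free text is
whitespace-normalized and casefolded) → direct `Maps to` relationship →
unmapped. All targets of a one-to-many entry are returned in crosswalk
order.

Classification concepts (MedDRA-like) can never be an event's
`concept_id`; they travel in `source_concept_id`. This is enforced
twice: `Maps to` targets must be standard at store construction, and a
linter refuses crosswalk targets whose domain has no event table.

Custom concepts are allocated sequentially from 2,000,000,000 (the OMOP
local-concept convention), deterministically given registration order,
and idempotently by (name, domain). Orphans are permitted — WHO
functional class has no standard parent to attach to. Registration never
touches pre-existing content (property tested).

The ancestor closure emits, for every ordered pair connected through
`Is a` edges, the shortest and longest path lengths as min/max levels
(both well defined on a DAG; longest path matches OMOP
`max_levels_of_separation` semantics), plus `(c, c, 0, 0)` self rows for
every concept — OMOP convention, adopted where the source material is
silent on self rows and multi-parent level semantics. Implementation is a
dynamic program over reverse topological order; cycles are fatal and
named. Its oracle in the tests is an exhaustive DFS path enumeration on
random DAGs of up to 50 nodes.

The bundled miniature vocabulary (~80 concepts) contains the real OMOP
ids for every concept the worked examples and
disposition/outcome/method patterns use, a synthetic SNOMED-like PH
hierarchy (PAH and CTEPH under pulmonary hypertension), MedDRA-like and
WHODrug-like source concepts, and the crosswalk connecting them.
Synthetic members live in documented private id ranges (36/37/39/42
million) because the real vocabularies cannot be redistributed; custom
concepts proper are registered through the normal path. For
`FACT_RELATIONSHIP` domain ids, the observation (1147304) and
measurement (1147330) table concepts are the standard ones; the
remaining tables use local metadata concepts in the custom range rather
than invented "standard" ids.

## Routing and linking

The target table is dictated by the resolved concept's domain — also for
medical history, where a term resolving to an Observation-domain concept
routes to `OBSERVATION` rather than `CONDITION_OCCURRENCE`; domain-driven
routing is the deterministic realization of case-by-case table choice.
One event row is emitted per resolved concept (fan-out conservation:
rows = resolution size, property tested). Unresolved records go to the
unmapped log.

Characteristics of an event (severity with its grade, causality with its
yes/no/possible/unlikely answer, method of measurement) become
observation rows — characteristic as `observation_concept_id`, assessment
as `value_as_concept_id`, same person and date — linked to the event by a
mirrored `FACT_RELATIONSHIP` pair (forward and inverse rows, same
relationship concept, facts and domain ids swapped). Non-fatal outcomes
use the outcome-categories observation pattern; fatal outcomes are not
events but death-date candidates. Disposition records (enrollment,
consent, completion, withdrawal) map to configurable observation
concepts, the study name in `value_as_string`, the discontinuation
reason as a value concept. Combination recipes (e.g. PAH + connective
tissue disease overlap syndrome for a subgroup the vocabulary cannot
express in one concept) emit one row per member with the qualifiers
linked to the primary.

Lineage is an explicit output: `provenance.csv` maps every event row to
its source (patient, domain, sequence) and marks rows *derived* from
another event (linked characteristics/outcomes/methods). QA record
counts use only non-derived rows — the fan-out footnote semantics
("CDM records can exceed source records because one source code maps to
several targets") would otherwise be inflated by linkage by-products.

## Quality assessment

Keys are fixed here because count tables rarely define them: a unique
source record is a distinct (patient, domain, sequence) triple; a unique
CDM record is a distinct non-derived event row (counted after fan-out); a
unique source value is a distinct (vocabulary, code-or-normalized-text)
pair. Category scope: conditions = AE + MH, drugs = CM + EX, over
retained patients.

Percentages use half-up decimal rounding: redundancy to the nearest
integer percent, patient accounting to one decimal — matching how such
tables are printed. The demographic consistency check derives age at
enrollment (enrollment year − birth year) and gender counts
independently on each side — the source side from DM minus the exclusion
log, the CDM side from PERSON plus the enrollment observations — and
flags count mismatches exactly and means/SDs beyond 0.01.

## The synthetic registry and what it does (not) show

The generator emulates study *structure*, not disease: clinically
arbitrary but structurally realistic content. Default conditions describe
a mid-sized prospective drug registry: 500 patients; 2% protocol
violators; 2% duplicate patient entries (a second patient id sharing the
sponsor person key); 1% each missing birth year / missing all treatment
dates; per-date missingness of 10% (day), 5% (day+month), 3% (entirely
missing); 10% free-text entries; 3% deliberately unmappable codes; 6%
deaths, 40% of them with conflicting death sources; a six-item condition
checklist with 50% non-occurrence in prospective mode — retrospective
mode records only events that occurred, emitting no non-occurrence rows.
Magnitudes are chosen to be typical of multi-centre PH registries (where
only a few percent of patients fail selection and non-occurrence
dominates prospective checklists); they are study conditions, not tuning
knobs.

Each (patient, domain) pair draws from its own seeded substream, so
adding a field or domain never perturbs another's values; identical
config and seed give byte-identical files.

Alongside the tables, the generator writes a ground-truth ledger: per
record, the true date, its expected concept targets, and whether it is a
non-event, unmappable, undatable, duplicate, or belongs to an excluded
patient. `expected_qa` turns the ledger into the exact accounting the
pipeline must reproduce; the closure test asserts equality — not
approximation — across seeds and both designs at n = 500. Duplicate
detection, precedence of exclusion reasons (violator ≻ duplicate ≻
missing birth year ≻ missing treatment dates), and the
resolve-then-date ordering of the record pipeline are mirrored exactly
in the ledger semantics; that mirroring is the contract the tests
enforce.

What passing these tests does *not* show: robustness to SDTM dialects
the generator does not emit (other date formats, other column layouts —
overridable via configuration but not fuzzed), to vocabulary content
beyond the bundled fixture, or to clinical plausibility of values. Lab
and vital-sign magnitudes are arbitrary; no longitudinal disease
trajectory exists to recover.

## Numerical and degenerate-input choices

* Rounding is decimal half-up throughout (`round_half_up`), never
  float banker's rounding.
* Zero source values make the redundancy percentage undefined; it is
  reported as not-applicable, never as 0 or 100.
* An event end date earlier than its (imputed) start is clamped to the
  start.
* A patient with death as their only fact still gets an observation
  period; a patient with no dated facts gets none.
* Duplicate DM rows for one patient collapse to the first with a
  row-level log entry; they do not reduce patient counts. Whole-patient
  duplicates (shared sponsor person key) are patient-level exclusions.
* Fully-missing dates with no timepoint anchor drop the record with a
  logged reason; nothing is invented.

## Known limitations

* The UMLS-assisted automated mapping that produces real crosswalks is
  represented by the crosswalk artifact itself, not re-implemented
  (licensing); the package consumes its product.
* Drug/condition era derivation, cost tables, visit detail, and
  DDL for specific database engines are out of scope.
* Inverse `FACT_RELATIONSHIP` rows reuse the forward relationship
  concept; OMOP's distinct inverse relationship ids would require
  vocabulary content the fixture does not carry.
* The `qa` CLI recomputes counts from written files via the lineage
  sidecar; without `provenance.csv` (e.g. on a foreign CDM instance) the
  per-category accounting cannot be reconstructed.
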