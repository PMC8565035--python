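"""OMOP vocabulary store: concepts, relationships, ancestry, crosswalk.

The store holds four collections mirroring the OMOP vocabulary tables:

* **concepts** — standard, classification (hierarchy-only, e.g. MedDRA),
  non-standard, and *custom* concepts.  Custom concepts carry local ids in
  the >= 2,000,000,000 range and exist only in this CDM instance.
* **relationships** — 'Maps to' (source -> standard translation) and
  'Is a' (hierarchical subsumption) edges, plus custom-labelled ones.
* **ancestors** — the transitive closure of 'Is a', with minimum and
  maximum level separations, including (c, c, 0, 0) self rows.
* **crosswalk** — the curated source-code -> standard-concept product of
  the (manual + automated) mapping review, shipped as data.

Source-to-standard resolution is deterministic: exact crosswalk entry
first, then a direct 'Maps to' relationship, else unmapped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

__all__ = [
    "CUSTOM_ID_START",
    "Concept",
    "ConceptRelationship",
    "ConceptAncestor",
    "CrosswalkEntry",
    "ConceptCombination",
    "VocabularyStore",
    "combine_concepts",
    "load_vocabulary",
]

CUSTOM_ID_START = 2_000_000_000

#: OMOP event-table routing by concept domain
DOMAIN_TO_TABLE = {
    "Condition": "condition_occurrence",
    "Drug": "drug_exposure",
    "Measurement": "measurement",
    "Observation": "observation",
    "Procedure": "procedure_occurrence",
    "Visit": "visit_occurrence",
}


@dataclass(frozen=True)
class Concept:
    concept_id: int
    name: str
    domain_id: str
    vocabulary_id: str
    standard_flag: str = "standard"  # standard | classification | non_standard
    is_custom: bool = False
    concept_code: str = ""

    def __post_init__(self) -> None:
        if self.standard_flag not in ("standard", "classification", "non_standard"):
            raise ValueError(f"bad standard_flag: {self.standard_flag}")
        if self.is_custom and self.concept_id < CUSTOM_ID_START:
            raise ValueError(
                f"custom concept id {self.concept_id} below {CUSTOM_ID_START}"
            )


@dataclass(frozen=True)
class ConceptRelationship:
    concept_id_1: int
    concept_id_2: int
    relationship_id: str  # 'Maps to', 'Is a', or custom-labelled


@dataclass(frozen=True)
class ConceptAncestor:
    ancestor_id: int
    descendant_id: int
    min_levels: int
    max_levels: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_levels <= self.max_levels):
            raise ValueError("require 0 <= min_levels <= max_levels")


@dataclass(frozen=True)
class CrosswalkEntry:
    source_vocabulary: str  # MedDRA, WHODrug, free-text
    source_code: str
    target_concept_ids: Tuple[int, ...]
    provenance: str = "manual"  # automated | manual | custom

    def __post_init__(self) -> None:
        if not self.target_concept_ids:
            raise ValueError("crosswalk entry with no targets")


@dataclass(frozen=True)
class ConceptCombination:
    """Recipe for representing one clinical entity as several linked rows.

    Disease subgroups absent from the standard vocabulary (e.g. PAH
    associated with connective tissue disease) are expressed as the primary
    condition plus qualifier condition(s); the ETL emits one event row per
    member and links them via FACT_RELATIONSHIP.
    """

    primary_id: int
    qualifier_ids: Tuple[int, ...] = ()

    @property
    def concept_ids(self) -> Tuple[int, ...]:
        return (self.primary_id,) + self.qualifier_ids


def _normalize_text(text: str) -> str:
    return " ".join(text.split()).casefold()


class VocabularyStore:
    """In-memory concept store with closure maintenance."""

    def __init__(self) -> None:
        self.concepts: Dict[int, Concept] = {}
        self.relationships: List[ConceptRelationship] = []
        self.ancestors: List[ConceptAncestor] = []
        self.crosswalk: Dict[Tuple[str, str], CrosswalkEntry] = {}
        self._closure_stale = True
        self._next_custom_id = CUSTOM_ID_START

    # -- construction -----------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise ValueError(f"duplicate concept id {concept.concept_id}")
        self.concepts[concept.concept_id] = concept
        if concept.is_custom and concept.concept_id >= self._next_custom_id:
            self._next_custom_id = concept.concept_id + 1

    def add_relationship(self, rel: ConceptRelationship) -> None:
        for cid in (rel.concept_id_1, rel.concept_id_2):
            if cid not in self.concepts:
                raise KeyError(f"relationship references unknown concept {cid}")
        if rel.relationship_id == "Maps to":
            target = self.concepts[rel.concept_id_2]
            if target.standard_flag != "standard":
                raise ValueError(
                    f"'Maps to' target {target.concept_id} is not standard"
                )
        self.relationships.append(rel)
        if rel.relationship_id == "Is a":
            self._closure_stale = True

    def add_crosswalk_entry(self, entry: CrosswalkEntry) -> None:
        for cid in entry.target_concept_ids:
            concept = self.concepts.get(cid)
            if concept is None:
                raise KeyError(f"crosswalk target {cid} not in store")
            if concept.standard_flag != "standard" and not concept.is_custom:
                raise ValueError(
                    f"crosswalk target {cid} is neither standard nor custom"
                )
        key = (entry.source_vocabulary, _normalize_text(entry.source_code))
        self.crosswalk[key] = entry

    # -- resolution -------------------------------------------------------

    def resolve_source(
        self, vocab: str, code_or_text: str
    ) -> Tuple[List[int], Optional[str]]:
        """Resolve a source code or verbatim text to standard concept ids.

        Returns ``(concept_ids, provenance)``; an empty list with ``None``
        provenance signals an unmapped source value (logged by the caller,
        never silently dropped).  One source code may map to several
        targets; all are returned in crosswalk order.
        """
        entry = self.crosswalk.get((vocab, _normalize_text(code_or_text)))
        if entry is not None:
            return list(entry.target_concept_ids), entry.provenance
        source = self._concept_by_code(vocab, code_or_text)
        if source is not None:
            targets = [
                r.concept_id_2
                for r in self.relationships
                if r.relationship_id == "Maps to"
                and r.concept_id_1 == source.concept_id
            ]
            if targets:
                return targets, "maps_to"
        return [], None

    def _concept_by_code(self, vocab: str, code: str) -> Optional[Concept]:
        for concept in self.concepts.values():
            if concept.vocabulary_id == vocab and concept.concept_code == code:
                return concept
        return None

    # -- custom concepts --------------------------------------------------

    def register_custom_concept(
        self,
        name: str,
        domain_id: str,
        parent_ids: Sequence[int] = (),
        vocabulary_id: str = "Custom",
    ) -> int:
        """Create (or return) a local concept in the >= 2e9 id range.

        Idempotent on (name, domain): re-registering returns the existing
        id.  Each parent gains an 'Is a' edge from the new concept; orphan
        customs (no parents) are permitted — e.g. gradings the standard
        vocabulary lacks entirely, such as WHO functional class.  The
        ancestor closure is marked stale, never silently rebuilt.
        """
        for concept in self.concepts.values():
            if (
                concept.is_custom
                and concept.name == name
                and concept.domain_id == domain_id
            ):
                return concept.concept_id
        for pid in parent_ids:
            parent = self.concepts.get(pid)
            if parent is None:
                raise KeyError(f"unknown parent concept {pid}")
            if parent.standard_flag != "standard" and not parent.is_custom:
                raise ValueError(f"parent {pid} is neither standard nor custom")
        cid = self._next_custom_id
        self._next_custom_id += 1
        self.add_concept(
            Concept(cid, name, domain_id, vocabulary_id, "standard", True, str(cid))
        )
        for pid in parent_ids:
            self.add_relationship(ConceptRelationship(cid, pid, "Is a"))
        return cid

    # -- ancestor closure -------------------------------------------------

    def is_a_graph(self) -> nx.DiGraph:
        """Directed graph with an edge child -> parent per 'Is a' row."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(
            (r.concept_id_1, r.concept_id_2)
            for r in self.relationships
            if r.relationship_id == "Is a"
        )
        return g

    def build_ancestor_closure(self) -> List[ConceptAncestor]:
        """(Re)build the CONCEPT_ANCESTOR transitive closure.

        For every ordered pair (ancestor, descendant) connected through
        'Is a' edges, emits the shortest- and longest-path lengths as
        min/max levels (both well defined on a DAG), plus a (c, c, 0, 0)
        self row for every concept.  A cycle is fatal and is named.
        """
        g = self.is_a_graph()
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"'Is a' hierarchy contains a cycle: {cycle}")

        # DP in reverse topological order so each parent's ancestor map is
        # final before its children merge it; dist[d] holds
        # {ancestor: (min, max)} path lengths from d upward.
        dist: Dict[int, Dict[int, Tuple[int, int]]] = {n: {} for n in g}
        for node in reversed(order):
            for parent in g.successors(node):
                merged = dist[node].setdefault(parent, (1, 1))
                dist[node][parent] = (min(merged[0], 1), max(merged[1], 1))
                for anc, (lo, hi) in dist[parent].items():
                    if anc in dist[node]:
                        plo, phi = dist[node][anc]
                        dist[node][anc] = (min(plo, lo + 1), max(phi, hi + 1))
                    else:
                        dist[node][anc] = (lo + 1, hi + 1)

        rows = [ConceptAncestor(c, c, 0, 0) for c in sorted(g.nodes)]
        for desc in sorted(g.nodes):
            for anc in sorted(dist[desc]):
                lo, hi = dist[desc][anc]
                rows.append(ConceptAncestor(anc, desc, lo, hi))
        self.ancestors = rows
        self._closure_stale = False
        return rows

    @property
    def closure_stale(self) -> bool:
        return self._closure_stale

    # -- linting ----------------------------------------------------------

    def lint_crosswalk_domains(self) -> List[str]:
        """Check every crosswalk target routes to a unique CDM event table."""
        problems = []
        for entry in self.crosswalk.values():
            for cid in entry.target_concept_ids:
                domain = self.concepts[cid].domain_id
                if domain not in DOMAIN_TO_TABLE and domain not in (
                    "Meas Value",
                    "Metadata",
                ):
                    problems.append(
                        f"{entry.source_vocabulary}:{entry.source_code} -> "
                        f"{cid} has unroutable domain {domain!r}"
                    )
        return problems

    # -- I/O (Athena-style tab-delimited layout) --------------------------

    def write(self, dir_path: Path | str) -> None:
        dir_path = Path(dir_path)
        dir_path.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            dir_path / "CONCEPT.csv",
            [
                "concept_id", "concept_name", "domain_id", "vocabulary_id",
                "standard_concept", "invalid_reason", "concept_code",
            ],
            [
                [
                    c.concept_id, c.name, c.domain_id, c.vocabulary_id,
                    {"standard": "S", "classification": "C", "non_standard": ""}[
                        c.standard_flag
                    ],
                    "", c.concept_code,
                ]
                for c in sorted(self.concepts.values(), key=lambda c: c.concept_id)
            ],
        )
        _write_tsv(
            dir_path / "CONCEPT_RELATIONSHIP.csv",
            ["concept_id_1", "concept_id_2", "relationship_id"],
            [[r.concept_id_1, r.concept_id_2, r.relationship_id] for r in self.relationships],
        )
        _write_tsv(
            dir_path / "CONCEPT_ANCESTOR.csv",
            [
                "ancestor_concept_id", "descendant_concept_id",
                "min_levels_of_separation", "max_levels_of_separation",
            ],
            [
                [a.ancestor_id, a.descendant_id, a.min_levels, a.max_levels]
                for a in self.ancestors
            ],
        )
        _write_tsv(
            dir_path / "crosswalk.tsv",
            ["source_vocabulary", "source_code", "target_concept_ids", "provenance"],
            [
                [
                    e.source_vocabulary, e.source_code,
                    "|".join(str(i) for i in e.target_concept_ids), e.provenance,
                ]
                for e in self.crosswalk.values()
            ],
        )


def _write_tsv(path: Path, header: List[str], rows: List[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        writer.writerows(rows)


def load_vocabulary(dir_path: Path | str) -> VocabularyStore:
    """Load CONCEPT / CONCEPT_RELATIONSHIP / CONCEPT_ANCESTOR / crosswalk."""
    dir_path = Path(dir_path)
    store = VocabularyStore()
    flag = {"S": "standard", "C": "classification", "": "non_standard"}
    with (dir_path / "CONCEPT.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            store.add_concept(
                Concept(
                    int(row["concept_id"]),
                    row["concept_name"],
                    row["domain_id"],
                    row["vocabulary_id"],
                    flag[row.get("standard_concept", "") or ""],
                    int(row["concept_id"]) >= CUSTOM_ID_START,
                    row.get("concept_code", ""),
                )
            )
    rel_path = dir_path / "CONCEPT_RELATIONSHIP.csv"
    if rel_path.exists():
        with rel_path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.add_relationship(
                    ConceptRelationship(
                        int(row["concept_id_1"]),
                        int(row["concept_id_2"]),
                        row["relationship_id"],
                    )
                )
    anc_path = dir_path / "CONCEPT_ANCESTOR.csv"
    if anc_path.exists():
        with anc_path.open(newline="", encoding="utf-8") as fh:
            store.ancestors = [
                ConceptAncestor(
                    int(row["ancestor_concept_id"]),
                    int(row["descendant_concept_id"]),
                    int(row["min_levels_of_separation"]),
                    int(row["max_levels_of_separation"]),
                )
                for row in csv.DictReader(fh, delimiter="\t")
            ]
            store._closure_stale = False
    xw_path = dir_path / "crosswalk.tsv"
    if xw_path.exists():
        with xw_path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                store.add_crosswalk_entry(
                    CrosswalkEntry(
                        row["source_vocabulary"],
                        row["source_code"],
                        tuple(
                            int(t) for t in row["target_concept_ids"].split("|")
                        ),
                        row["provenance"],
                    )
                )
    return store


def combine_concepts(
    primary_id: int, qualifier_ids: Sequence[int], store: VocabularyStore
) -> ConceptCombination:
    """Build a multi-concept recipe for an entity needing differentiation.

    An empty qualifier list yields the trivial singleton recipe.
    """
    for cid in (primary_id, *qualifier_ids):
        if cid not in store.concepts:
            raise KeyError(f"unknown concept {cid}")
    return ConceptCombination(primary_id, tuple(qualifier_ids))
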