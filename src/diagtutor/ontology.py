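"""Concept ontology with Jaccard text matching and graph path distance.

Free-text diagnostic hypotheses are linked to ontology concepts by Jaccard
similarity over stop-word-filtered token sets (labels and synonyms), and a
student hypothesis is graded against the case's reference hypotheses by the
shortest-path edge count in the is-a hierarchy: distance 0 is *correct*,
distances 1-4 are *close*, and anything farther (or disconnected) is
*incorrect*.  The hierarchy is traversed as an undirected graph because the
grading rule counts edges on any connecting path.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Concept",
    "Ontology",
    "MatchResult",
    "load_stopwords",
    "default_stopwords",
    "normalize_tokens",
    "jaccard",
    "match_concept",
    "path_distance",
    "classify_hypothesis",
    "is_ancestor",
    "load_ontology",
    "load_snomed_rf2",
]

_TOKEN_RE = re.compile(r"[^0-9a-z]+")

#: SNOMED CT relationship type id for |is a|, used by the RF2 adapter.
_RF2_IS_A = "116680003"
_RF2_FSN = "900000000000003001"


@dataclass(frozen=True)
class Concept:
    """A single ontology concept: preferred label, synonyms, is-a parents."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"concept {self.id!r} has an empty label")
        if self.id in self.parents:
            raise ValueError(f"concept {self.id!r} lists itself as a parent")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of grading one free-text hypothesis against the references.

    ``verdict`` is ``correct`` (distance 0), ``close`` (1-4), ``incorrect``
    (>= 5 or disconnected) or ``unrecognized`` (no concept matched the text).
    """

    matched_concept_id: str | None
    nearest_reference_id: str | None
    distance: float
    verdict: str


class Ontology:
    """A validated is-a concept graph supporting distance and ancestor queries."""

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise ValueError(f"duplicate concept id {c.id!r}")
            self.concepts[c.id] = c
        if not self.concepts:
            raise ValueError("ontology contains no concepts")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise ValueError(
                        f"concept {c.id!r} references unknown parent {p!r}"
                    )
                dag.add_edge(c.id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise ValueError(f"is-a relation contains a cycle: {cycle}")
        self._dag = dag
        self._graph = dag.to_undirected(as_view=False)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept id {concept_id!r}") from None

    @property
    def graph(self) -> nx.Graph:
        """Undirected view of the is-a edges (used for path distance)."""
        return self._graph

    def ancestors(self, concept_id: str) -> set[str]:
        """All concepts reachable from ``concept_id`` by parent links."""
        self[concept_id]
        return nx.descendants(self._dag, concept_id)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-word-per-line UTF-8 stop-word list."""
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.strip().lower() for w in words if w.strip())


def default_stopwords() -> frozenset[str]:
    """The stop-word list shipped with the package."""
    text = resources.files("diagtutor.data").joinpath("stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(w.lower() for w in text.split() if w)


def normalize_tokens(text: str, stopwords: frozenset[str] | set[str]) -> frozenset[str]:
    """Lowercase, strip punctuation, split, and drop stop words.

    Returns a set, so repeated words collapse; an empty text yields an empty
    set.  No stemming is applied here — exact token overlap is what the
    concept matcher scores.
    """
    tokens = _TOKEN_RE.split(text.lower())
    return frozenset(t for t in tokens if t and t not in stopwords)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b|, with jaccard(∅, ∅) defined as 0."""
    if not a and not b:
        return 0.0
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def match_concept(
    text: str,
    ont: Ontology,
    min_sim: float = 0.2,
    stopwords: frozenset[str] | None = None,
) -> tuple[str | None, float]:
    """Best-matching concept for a free-text string, or ``None`` below ``min_sim``.

    Every concept is scored by the maximum Jaccard similarity between the
    input tokens and the tokens of its label or any synonym.  Ties are broken
    by the lexicographically smallest concept id so matching is deterministic.
    """
    if len(ont) == 0:  # pragma: no cover - Ontology forbids this at build time
        raise ValueError("cannot match against an empty ontology")
    if stopwords is None:
        stopwords = default_stopwords()
    query = normalize_tokens(text, stopwords)
    best_id: str | None = None
    best_sim = -1.0
    for cid in sorted(ont.concepts):
        concept = ont.concepts[cid]
        sim = max(
            jaccard(query, normalize_tokens(t, stopwords))
            for t in (concept.label, *concept.synonyms)
        )
        if sim > best_sim:
            best_id, best_sim = cid, sim
    best_sim = max(best_sim, 0.0)
    if best_sim < min_sim:
        return None, best_sim
    return best_id, best_sim


def path_distance(ont: Ontology, c1: str, c2: str) -> float:
    """Minimum number of is-a edges on any path between two concepts.

    Symmetric by construction (the graph is undirected); ``math.inf`` when the
    concepts lie in disconnected components.
    """
    for cid in (c1, c2):
        if cid not in ont:
            raise KeyError(f"unknown concept id {cid!r}")
    try:
        return float(nx.shortest_path_length(ont.graph, c1, c2))
    except nx.NetworkXNoPath:
        return math.inf


def _verdict_for(distance: float) -> str:
    if distance == 0:
        return "correct"
    if 1 <= distance <= 4:
        return "close"
    return "incorrect"


def classify_hypothesis(
    text: str,
    references: list[str],
    ont: Ontology,
    min_sim: float = 0.2,
    stopwords: frozenset[str] | None = None,
) -> MatchResult:
    """Grade a free-text diagnostic hypothesis against the reference list.

    The text is linked to its best-matching concept; the verdict comes from the
    minimum path distance to any reference: 0 → correct, 1-4 → close,
    5 or more (including disconnected) → incorrect.  When no concept clears
    ``min_sim`` the verdict is ``unrecognized`` and the caller should prompt
    the student to rephrase.
    """
    if not references:
        raise ValueError("reference hypothesis list is empty")
    for r in references:
        if r not in ont:
            raise KeyError(f"reference hypothesis {r!r} not in ontology")
    matched, _sim = match_concept(text, ont, min_sim=min_sim, stopwords=stopwords)
    if matched is None:
        return MatchResult(None, None, math.inf, "unrecognized")
    best_ref: str | None = None
    best_dist = math.inf
    for ref in sorted(references):
        d = path_distance(ont, matched, ref)
        if d < best_dist:
            best_ref, best_dist = ref, d
    return MatchResult(matched, best_ref, best_dist, _verdict_for(best_dist))


def is_ancestor(ont: Ontology, a: str, b: str) -> bool:
    """True iff ``a`` lies on ``b``'s parent chain (irreflexive)."""
    for cid in (a, b):
        if cid not in ont:
            raise KeyError(f"unknown concept id {cid!r}")
    if a == b:
        return False
    return a in ont.ancestors(b)


def load_ontology(concepts_path: str | Path, edges_path: str | Path) -> Ontology:
    """Load an ontology from two tab-separated files.

    ``concepts_path``: one concept per line — ``id<TAB>label<TAB>syn1|syn2``
    (the synonym column may be empty).  ``edges_path``: one is-a edge per
    line — ``child_id<TAB>parent_id``.  Acyclicity and referential integrity
    are validated on load.
    """
    parents: dict[str, list[str]] = {}
    for line in Path(edges_path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        try:
            child, parent = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"malformed edge line {line!r}") from exc
        parents.setdefault(child.strip(), []).append(parent.strip())
    concepts = []
    for line in Path(concepts_path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed concept line {line!r}")
        cid = fields[0].strip()
        label = fields[1].strip()
        syns = tuple(
            s.strip() for s in (fields[2].split("|") if len(fields) > 2 else []) if s.strip()
        )
        concepts.append(
            Concept(cid, label, syns, tuple(parents.get(cid, ())))
        )
    return Ontology(concepts)


def load_snomed_rf2(
    concept_file: str | Path,
    description_file: str | Path,
    relationship_file: str | Path,
) -> Ontology:
    """Adapter for SNOMED CT RF2 snapshot files (concepts, descriptions, is-a).

    The licensed SNOMED CT distribution is not bundled; this reads the
    standard RF2 tab-separated snapshot layout so a locally licensed release
    (or a synthetic stand-in with the same columns) can be loaded.  Only
    active rows and |is a| relationships are used; the fully specified name
    becomes the label, other descriptions become synonyms.
    """

    def _rows(path: str | Path) -> list[dict[str, str]]:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        return [dict(zip(header, ln.split("\t"))) for ln in lines[1:] if ln.strip()]

    active_ids = {
        r["id"] for r in _rows(concept_file) if r.get("active") == "1"
    }
    labels: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for r in _rows(description_file):
        if r.get("active") != "1" or r["conceptId"] not in active_ids:
            continue
        if r.get("typeId") == _RF2_FSN:
            labels.setdefault(r["conceptId"], r["term"])
        else:
            synonyms.setdefault(r["conceptId"], []).append(r["term"])
    parents: dict[str, list[str]] = {}
    for r in _rows(relationship_file):
        if r.get("active") != "1" or r.get("typeId") != _RF2_IS_A:
            continue
        if r["sourceId"] in active_ids and r["destinationId"] in active_ids:
            parents.setdefault(r["sourceId"], []).append(r["destinationId"])
    concepts = [
        Concept(
            cid,
            labels.get(cid) or (synonyms.get(cid) or ["concept " + cid])[0],
            tuple(synonyms.get(cid, ())),
            tuple(parents.get(cid, ())),
        )
        for cid in sorted(active_ids)
    ]
    return Ontology(concepts)
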