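"""Tissue ontology handling.

Tissue vocabularies such as the Brenda Tissue Ontology are directed acyclic
graphs of terms connected by is-a relations.  Different expression datasets
describe tissues at different resolution (whole brain vs. individual brain
regions), so every term is back-mapped onto a fixed set of mutually
non-ancestral "major" tissues before datasets are compared.

Parsing is delegated to :mod:`obonet`; this module keeps only is_a edges,
drops obsolete terms, verifies acyclicity and builds case-insensitive
name/synonym indexes for resolving free-text tissue labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyDAG",
    "MajorTissueSet",
    "OboError",
    "parse_obo",
    "match_tissue_name",
    "ancestors",
    "map_to_major",
    "assert_non_overlapping",
    "AMBIGUOUS_TISSUE_NAMES",
]


class OboError(ValueError):
    """Raised for malformed or cyclic ontology input."""


#: free-text labels that cannot be resolved to a single tissue and are
#: therefore never matched (extendable via the ``ambiguous`` argument of
#: :func:`match_tissue_name`)
AMBIGUOUS_TISSUE_NAMES = frozenset({"retina and testis", "uncharacterized tissue"})

_SYNONYM_RE = re.compile(r'"([^"]*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term: accession, canonical label, synonyms."""

    id: str
    name: str
    synonyms: tuple = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise OboError(f"term {self.id!r} has an empty name")


class OntologyDAG:
    """Tissue terms plus child->parent is-a edges, guaranteed acyclic."""

    def __init__(self, terms: Iterable[OntologyTerm], edges: Iterable[tuple]) -> None:
        self.terms = {}
        for term in terms:
            if term.id in self.terms:
                raise OboError(f"duplicate term id {term.id!r}")
            self.terms[term.id] = term
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OboError(f"is_a edge references unknown term {endpoint!r}")
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            member = nx.find_cycle(graph)[0][0]
            raise OboError(f"cyclic is_a relations involving term {member!r}")
        self.graph = graph
        # case-insensitive lookup: canonical names shadow synonyms
        self._name_index = {}
        self._synonym_index = {}
        for tid in sorted(self.terms):
            term = self.terms[tid]
            self._name_index.setdefault(term.name.strip().lower(), tid)
            for syn in term.synonyms:
                self._synonym_index.setdefault(syn.strip().lower(), tid)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> set:
        """Transitive is-a closure of ``term_id``, excluding itself."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        # edges point child -> parent, so graph-descendants are ancestors
        return set(nx.descendants(self.graph, term_id))


@dataclass(frozen=True)
class MajorTissueSet:
    """A fixed list of non-overlapping major-tissue term ids (nominally 21)."""

    terms: tuple

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("major tissue set contains duplicates")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_file(cls, path: str | Path) -> "MajorTissueSet":
        lines = Path(path).read_text().splitlines()
        return cls(tuple(ln.strip() for ln in lines if ln.strip()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{t}\n" for t in self.terms))


def parse_obo(source) -> OntologyDAG:
    """Parse OBO 1.2-style text into an :class:`OntologyDAG`.

    ``source`` may be a path or an open text handle.  One term per
    ``[Term]`` stanza, one edge per ``is_a`` line; obsolete terms are
    dropped; relationship types other than is_a are ignored.
    """
    try:
        graph = obonet.read_obo(source, ignore_obsolete=True)
    except OboError:
        raise
    except Exception as exc:  # malformed stanza, bad header, ...
        raise OboError(f"malformed OBO input: {exc}") from exc

    terms = []
    for node, attrs in graph.nodes(data=True):
        name = attrs.get("name")
        if not name:
            raise OboError(f"is_a edge references unknown term {node!r}")
        synonyms = []
        for raw in attrs.get("synonym", ()):
            m = _SYNONYM_RE.search(raw)
            synonyms.append(m.group(1) if m else raw.strip())
        terms.append(OntologyTerm(node, name, tuple(synonyms)))
    edges = [(c, p) for c, p, key in graph.edges(keys=True) if key == "is_a"]
    return OntologyDAG(terms, edges)


def match_tissue_name(
    name: str,
    dag: OntologyDAG,
    ambiguous: frozenset = AMBIGUOUS_TISSUE_NAMES,
) -> Optional[str]:
    """Resolve a free-text tissue label to a term id, or ``None``.

    Matching is case-insensitive and exact, first against canonical names
    and then against synonyms; labels on the ambiguous blacklist (e.g.
    "retina and testis") are never matched.  No fuzzy matching: an invented
    association is worse than a missing one.
    """
    if not name:
        raise ValueError("tissue name must be non-empty")
    key = name.strip().lower()
    if key in ambiguous:
        return None
    hit = dag._name_index.get(key)
    if hit is not None:
        return hit
    return dag._synonym_index.get(key)


def ancestors(term_id: str, dag: OntologyDAG) -> set:
    """Transitive is-a closure of ``term_id`` (excluding itself)."""
    return dag.ancestors(term_id)


def map_to_major(term_id: str, majors: MajorTissueSet, dag: OntologyDAG) -> set:
    """Back-map ``term_id`` to every major tissue it equals or descends from.

    A term may map to several majors in a DAG (multiple is-a paths); it then
    contributes to each of them.  Returns the empty set when no major is on
    any ancestor path.
    """
    anc = dag.ancestors(term_id)
    return {m for m in majors if m == term_id or m in anc}


def assert_non_overlapping(majors: MajorTissueSet, dag: OntologyDAG) -> bool:
    """True iff no major tissue is an ancestor of another major tissue."""
    for m in majors:
        if m not in dag:
            raise KeyError(f"unknown major tissue term {m!r}")
    member_set = set(majors)
    for m in majors:
        if dag.ancestors(m) & member_set:
            return False
    return True
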