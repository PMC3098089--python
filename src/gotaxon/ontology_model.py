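"""Core ontology graph model shared by the GO side and the taxonomy side.

Both the Gene Ontology fragment being checked and the NCBI-style taxonomy
are represented by the same structure: a set of terms (CURIE-identified
classes) plus typed directed edges.  Only three relations propagate
annotations and constraints — ``is_a``, ``part_of`` and ``occurs_in`` —
and the sub-graph they induce must be acyclic (the "true path rule"
guarantees upward propagation terminates).  Regulates-family edges are
stored but never propagated over: regulation can cross species, so a
constraint on a regulated process says nothing about its regulator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator

import networkx as nx

__all__ = [
    "RelationKind",
    "PROPAGATING_RELATIONS",
    "Term",
    "Edge",
    "OntologyGraph",
    "GraphIssue",
    "TermNotFoundError",
    "direct_parents",
    "validate_graph",
]


class RelationKind(enum.Enum):
    """Edge labels understood by the system.

    ``REGULATES_FAMILY`` covers ``regulates`` and its positive/negative
    sub-relations; these are never composed or propagated over.
    ``ONLY_IN_TAXON`` / ``NEVER_IN_TAXON`` anchor taxon constraints and
    ``UNION_OF`` links a union taxon to its members; all three are
    handled by the checker/taxonomy modules, not by graph traversal.
    """

    IS_A = "is_a"
    PART_OF = "part_of"
    OCCURS_IN = "occurs_in"
    REGULATES_FAMILY = "regulates"
    ONLY_IN_TAXON = "only_in_taxon"
    NEVER_IN_TAXON = "never_in_taxon"
    UNION_OF = "union_of"

    def __lt__(self, other: "RelationKind") -> bool:
        if not isinstance(other, RelationKind):
            return NotImplemented
        return self.value < other.value


#: Relations over which annotations and constraints propagate.
PROPAGATING_RELATIONS = frozenset(
    {RelationKind.IS_A, RelationKind.PART_OF, RelationKind.OCCURS_IN}
)

#: Relations returned by :func:`direct_parents` (hierarchy + stored regulates).
_PARENT_RELATIONS = PROPAGATING_RELATIONS | {RelationKind.REGULATES_FAMILY}


class TermNotFoundError(KeyError):
    """Raised when an operation references a term id absent from the graph."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError repr-quotes its arg; we want prose
        return f"term not found: {self.term_id}"


@dataclass(frozen=True)
class Term:
    """One ontology class.

    ``extras`` preserves unrecognised stanza lines verbatim so that OBO
    round-trips are lossless even for tags this tool does not interpret.
    """

    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False
    extras: tuple[str, ...] = ()


@dataclass(frozen=True, order=True)
class Edge:
    subject: str
    relation: RelationKind
    object: str


@dataclass(frozen=True)
class GraphIssue:
    """One structural problem found by :func:`validate_graph`."""

    kind: str  # 'cycle' | 'dangling' | 'obsolete_with_edges' | 'duplicate_edge' | 'self_loop'
    detail: str
    terms: tuple[str, ...] = ()


class OntologyGraph:
    """Terms plus typed directed edges.

    Edges are stored per-subject for fast parent lookup; duplicate edges
    and self-loops on hierarchy relations are rejected at insertion time.
    """

    def __init__(self) -> None:
        self.terms: dict[str, Term] = {}
        self._out: dict[str, list[Edge]] = {}
        self._edge_set: set[Edge] = set()

    # -- construction -------------------------------------------------

    def add_term(self, term: Term) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id: {term.id}")
        self.terms[term.id] = term

    def add_edge(self, subject: str, relation: RelationKind, obj: str) -> None:
        edge = Edge(subject, relation, obj)
        if edge in self._edge_set:
            raise ValueError(f"duplicate edge: {subject} {relation.value} {obj}")
        if subject == obj and relation in PROPAGATING_RELATIONS:
            raise ValueError(f"self-loop on {relation.value}: {subject}")
        self._edge_set.add(edge)
        self._out.setdefault(subject, []).append(edge)

    def copy(self) -> "OntologyGraph":
        dup = OntologyGraph()
        dup.terms = dict(self.terms)
        dup._out = {k: list(v) for k, v in self._out.items()}
        dup._edge_set = set(self._edge_set)
        return dup

    # -- access -------------------------------------------------------

    @property
    def edges(self) -> list[Edge]:
        """All edges in deterministic (sorted) order."""
        return sorted(self._edge_set)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def require(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise TermNotFoundError(term_id) from None

    def out_edges(self, term_id: str) -> list[Edge]:
        return sorted(self._out.get(term_id, ()))

    def iter_edges(self, *relations: RelationKind) -> Iterator[Edge]:
        wanted = set(relations) if relations else None
        for edge in self.edges:
            if wanted is None or edge.relation in wanted:
                yield edge

    def propagating_digraph(self) -> nx.DiGraph:
        """The is_a/part_of/occurs_in sub-graph as a networkx DiGraph.

        Every term appears as a node even if isolated, so reachability
        queries on constraint-free leaves are well defined.
        """
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        dg.add_edges_from(
            (e.subject, e.object, {"relation": e.relation})
            for e in self._edge_set
            if e.relation in PROPAGATING_RELATIONS
        )
        return dg

    def rename(self, term_id: str, **changes) -> None:
        self.terms[term_id] = replace(self.require(term_id), **changes)


def direct_parents(
    graph: OntologyGraph, term_id: str
) -> list[tuple[RelationKind, str]]:
    """Asserted hierarchy parents of ``term_id``: (relation, parent-id) pairs.

    Includes regulates-family edges (they are asserted structure) but never
    taxon-constraint or union edges; sorted for reproducible output.
    """
    graph.require(term_id)
    return sorted(
        (e.relation, e.object)
        for e in graph.out_edges(term_id)
        if e.relation in _PARENT_RELATIONS
    )


def validate_graph(graph: OntologyGraph) -> list[GraphIssue]:
    """Structural validation: cycles, dangling references, obsolete edges.

    Returns one issue per cycle in the propagating sub-graph (reported as
    the strongly connected component involved), one per edge endpoint that
    does not resolve to a declared term, and one per obsolete term that
    still carries outgoing edges.  An empty list means the graph satisfies
    all invariants, in particular that a topological order of the
    is_a/part_of/occurs_in sub-graph exists.
    """
    issues: list[GraphIssue] = []

    for edge in graph.edges:
        for endpoint in (edge.subject, edge.object):
            if endpoint not in graph.terms:
                issues.append(
                    GraphIssue(
                        "dangling",
                        f"edge {edge.subject} {edge.relation.value} {edge.object} "
                        f"references undeclared term {endpoint}",
                        (endpoint,),
                    )
                )

    dg = graph.propagating_digraph()
    for component in nx.strongly_connected_components(dg):
        members = tuple(sorted(component))
        if len(members) > 1:
            issues.append(
                GraphIssue(
                    "cycle",
                    "cycle among " + ", ".join(members),
                    members,
                )
            )

    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        if term.obsolete and graph.out_edges(term_id):
            issues.append(
                GraphIssue(
                    "obsolete_with_edges",
                    f"obsolete term {term_id} carries outgoing edges",
                    (term_id,),
                )
            )

    return issues
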