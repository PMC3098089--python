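"""Relation-composition inference over the ontology graph.

Two distinct questions are answered here.

*What named relation holds between two classes?* — answered by folding a
composition table along edge paths.  The base table holds exactly the
five binary rules that follow from the formal relation definitions:

    is_a . is_a      -> is_a
    is_a . part_of   -> part_of
    part_of . is_a   -> part_of
    is_a . occurs_in -> occurs_in
    occurs_in . is_a -> occurs_in

``part_of . part_of -> part_of`` is a consequence of part_of transitivity
and is enabled by default as an extension flag; two further compositions
involving occurs_in are available behind flags for experimentation and
default to off.  A chain whose fold hits an undefined pair entails no
named relation.

*Which classes does an annotation propagate to?* — plain reachability
over is_a/part_of/occurs_in edges, because annotation propagation
recurses over single edges rather than composed relations.  Violation
checking depends only on this closure, so the extension flags never
change which annotations are flagged.

Regulates-family edges take part in neither question.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

from .ontology_model import (
    PROPAGATING_RELATIONS,
    OntologyGraph,
    RelationKind,
)

__all__ = [
    "CompositionTable",
    "RegulatesNotComposableError",
    "compose",
    "entailed_relations",
    "propagation_closure",
]

_R = RelationKind

_BASE_TABLE: dict[tuple[RelationKind, RelationKind], RelationKind] = {
    (_R.IS_A, _R.IS_A): _R.IS_A,
    (_R.IS_A, _R.PART_OF): _R.PART_OF,
    (_R.PART_OF, _R.IS_A): _R.PART_OF,
    (_R.IS_A, _R.OCCURS_IN): _R.OCCURS_IN,
    (_R.OCCURS_IN, _R.IS_A): _R.OCCURS_IN,
}


class RegulatesNotComposableError(ValueError):
    """Regulates edges are never composed; asking is a caller bug."""


@dataclass(frozen=True)
class CompositionTable:
    """The binary relation-composition table plus optional extensions.

    Parameters
    ----------
    part_of_transitive:
        Adds ``part_of . part_of -> part_of``.  On by default: part_of is
        transitive by definition even though the pair is absent from the
        minimal rule list.
    occurs_in_over_part_of:
        Adds ``occurs_in . part_of -> occurs_in`` (off by default).
    occurs_in_transitive:
        Adds ``occurs_in . occurs_in -> occurs_in`` (off by default).
    """

    part_of_transitive: bool = True
    occurs_in_over_part_of: bool = False
    occurs_in_transitive: bool = False

    @property
    def entries(self) -> dict[tuple[RelationKind, RelationKind], RelationKind]:
        table = dict(_BASE_TABLE)
        if self.part_of_transitive:
            table[(_R.PART_OF, _R.PART_OF)] = _R.PART_OF
        if self.occurs_in_over_part_of:
            table[(_R.OCCURS_IN, _R.PART_OF)] = _R.OCCURS_IN
        if self.occurs_in_transitive:
            table[(_R.OCCURS_IN, _R.OCCURS_IN)] = _R.OCCURS_IN
        return table


def compose(
    table: CompositionTable, r1: RelationKind, r2: RelationKind
) -> RelationKind | None:
    """Compose two relations; ``None`` means the chain entails nothing named."""
    for r in (r1, r2):
        if r is _R.REGULATES_FAMILY:
            raise RegulatesNotComposableError(
                "regulates not composable: regulation may cross species"
            )
        if r not in PROPAGATING_RELATIONS:
            raise ValueError(f"{r.value} is not a composable relation")
    return table.entries.get((r1, r2))


def entailed_relations(
    graph: OntologyGraph,
    term_id: str,
    table: CompositionTable | None = None,
) -> set[tuple[str, RelationKind]]:
    """All (ancestor, relation) pairs entailed for ``term_id``.

    For every directed path from the term over is_a/part_of/occurs_in
    edges whose left-fold under :func:`compose` is defined, the path
    endpoint appears with the folded relation.  Computed by memoised
    traversal over the acyclic graph rather than path enumeration; on a
    DAG the two agree because the table is associative wherever defined.
    """
    if table is None:
        table = CompositionTable()
    graph.require(term_id)
    entries = table.entries

    # Worklist over (node, folded-relation) states: a state means some
    # path from term_id reaches `node` with that left-fold.  State-based
    # memoisation keeps left-fold semantics exact even for extension-flag
    # tables that are not associative, where folding path suffixes first
    # would differ.
    seen: set[tuple[str, RelationKind]] = set()
    frontier: list[tuple[str, RelationKind]] = []
    for edge in graph.out_edges(term_id):
        if edge.relation in PROPAGATING_RELATIONS:
            state = (edge.object, edge.relation)
            if state not in seen:
                seen.add(state)
                frontier.append(state)
    while frontier:
        node, folded = frontier.pop()
        for edge in graph.out_edges(node):
            if edge.relation not in PROPAGATING_RELATIONS:
                continue
            new_fold = entries.get((folded, edge.relation))
            if new_fold is None:
                continue
            state = (edge.object, new_fold)
            if state not in seen:
                seen.add(state)
                frontier.append(state)
    return seen


def propagation_closure(graph: OntologyGraph, term_id: str) -> set[str]:
    """The term plus everything reachable over is_a/part_of/occurs_in.

    This is the set of classes an annotation to ``term_id`` is entailed
    for (the true path rule).  Regulates edges are never traversed.
    """
    graph.require(term_id)
    dg = graph.propagating_digraph()
    return {term_id} | nx.descendants(dg, term_id)
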