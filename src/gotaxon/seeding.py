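"""Heuristic seeding of candidate taxon constraints from annotation data.

A GO class that has never been used for gene products of one clade, but
is well supported in that clade's sister clades, is a *candidate* for a
never_in_taxon constraint on the unannotated clade.  The signal is weak
— absence of annotation routinely reflects absence of curation effort,
not absence of biology (a class annotated only in Arabidopsis says
nothing about other plants) — so every candidate is explicitly labelled
as requiring manual vetting and carries its supporting counts.

Counts use the propagation closure: an annotation to a specific class
supports every ancestor class it is entailed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .checker import Annotation, ConstraintKind, TaxonConstraint, effective_constraints
from .ontology_model import OntologyGraph
from .taxonomy import TaxonomyTree, in_taxon

__all__ = ["CandidateConstraint", "suggest_constraints", "write_candidates"]

VETTING_NOTE = "requires manual vetting"


@dataclass(frozen=True)
class CandidateConstraint:
    """A proposed never_in constraint with its supporting evidence counts."""

    go_class: str
    go_name: str
    kind: ConstraintKind
    focus_taxon: str
    focus_count: int  # closure-propagated annotations from inside the focus clade
    sister_count: int  # ditto from the sister clades
    note: str = VETTING_NOTE

    def as_constraint(self) -> TaxonConstraint:
        return TaxonConstraint(self.go_class, self.kind, self.focus_taxon)


def _already_excluded(
    go_graph: OntologyGraph,
    constraints: list[TaxonConstraint],
    go_class: str,
    focus_taxon: str,
    full_tree: TaxonomyTree,
) -> bool:
    """Does an effective constraint already bar the focus clade from the class?

    Equal-or-stricter means: a never_in whose taxon covers the focus
    clade, or an only_in whose taxon is disjoint from it (neither
    contains the other), so no focus species could ever pass.
    """
    for constraint, _path in effective_constraints(go_graph, constraints, go_class):
        if constraint.taxon not in full_tree:
            continue
        if constraint.kind is ConstraintKind.NEVER_IN:
            if in_taxon(full_tree, focus_taxon, constraint.taxon):
                return True
        else:
            covers = in_taxon(full_tree, focus_taxon, constraint.taxon)
            nested_under_focus = not full_tree.is_union(
                constraint.taxon
            ) and in_taxon(full_tree, constraint.taxon, focus_taxon)
            if not covers and not nested_under_focus:
                return True
    return False


def suggest_constraints(
    go_graph: OntologyGraph,
    annotations: list[Annotation],
    full_tree: TaxonomyTree,
    focus_taxon: str,
    min_sister_annotations: int,
    existing_constraints: list[TaxonConstraint] = (),
) -> list[CandidateConstraint]:
    """Classes unannotated under ``focus_taxon`` but annotated in its sisters.

    For every GO class, annotations are counted closure-propagated (an
    annotation supports the class and all its ancestors).  A class with
    zero support from species under the focus clade and at least
    ``min_sister_annotations`` from species under sister clades (the
    other children of the focus clade's parent) yields a
    never_in(focus_taxon) candidate.  Classes already barred by an
    equal-or-stricter existing constraint are skipped.  Sorted by class
    id; the focus clade must not be the taxonomy root.
    """
    parent = full_tree.parent(focus_taxon)
    if parent is None:
        raise ValueError(f"{focus_taxon} is a root taxon and has no sisters")
    sisters = sorted(
        e.subject
        for e in full_tree.graph.iter_edges()
        if e.object == parent
        and e.relation.value == "is_a"
        and e.subject != focus_taxon
        and not full_tree.is_union(e.subject)
    )
    if not sisters:
        raise ValueError(f"{focus_taxon} has no sister taxa under {parent}")

    dg = go_graph.propagating_digraph()
    focus_support: dict[str, int] = {}
    sister_support: dict[str, int] = {}
    for annotation in annotations:
        if annotation.go_class not in go_graph or annotation.taxon not in full_tree:
            continue
        if in_taxon(full_tree, annotation.taxon, focus_taxon):
            bucket = focus_support
        elif any(in_taxon(full_tree, annotation.taxon, s) for s in sisters):
            bucket = sister_support
        else:
            continue
        closure = {annotation.go_class} | nx.descendants(dg, annotation.go_class)
        for cls in closure:
            bucket[cls] = bucket.get(cls, 0) + 1

    candidates = []
    for go_class in sorted(go_graph.terms):
        if not go_class.startswith("GO:") or go_graph.terms[go_class].obsolete:
            continue
        focus_n = focus_support.get(go_class, 0)
        sister_n = sister_support.get(go_class, 0)
        if focus_n == 0 and sister_n >= min_sister_annotations:
            if _already_excluded(
                go_graph, list(existing_constraints), go_class, focus_taxon, full_tree
            ):
                continue
            candidates.append(
                CandidateConstraint(
                    go_class=go_class,
                    go_name=go_graph.terms[go_class].name,
                    kind=ConstraintKind.NEVER_IN,
                    focus_taxon=focus_taxon,
                    focus_count=focus_n,
                    sister_count=sister_n,
                )
            )
    return candidates


def write_candidates(candidates, stream=None) -> str | None:
    """TSV candidate report; the verdict column is left blank for curators."""
    lines = ["go_class\tgo_name\tkind\tfocus_taxon\tfocus_count\tsister_count\tnote\tverdict"]
    for c in candidates:
        lines.append(
            f"{c.go_class}\t{c.go_name}\t{c.kind.value}\t{c.focus_taxon}"
            f"\t{c.focus_count}\t{c.sister_count}\t{c.note}\t"
        )
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None
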