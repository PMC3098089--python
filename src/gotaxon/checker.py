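"""The violation engine.

A taxon constraint ties a GO class to a taxonomic group:

* ``only_in_taxon(A, T)`` — A, its sub-types and its parts may annotate
  only gene products whose species lies in T (or a sub-type of T);
* ``never_in_taxon(A, T)`` — A, its sub-types and its parts may never
  annotate gene products whose species lies in T.

Constraints are inherited downwards by sub-types and parts, which is the
mirror image of annotation propagation upwards: an annotation to class C
is entailed for every class in the propagation closure of C, so any
constraint asserted on a closure member applies.  Both readings are
implemented — constraints pushed down to classes
(:class:`ConstraintIndex`) and annotations walked up
(:func:`check_annotation`) — and are cross-checked in the test suite.

Negation is closed-world: ``not in_taxon(G, T)`` holds exactly when T is
absent from the is_a closure of G's taxon, matching negation-as-failure
semantics.  Multiple constraints along the closure are conjunctive: an
annotation must satisfy all of them, and every violated constraint is
reported (a class narrowed to Viridiplantae is checked against both the
narrow constraint and the broader union constraint it refines).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .ontology_model import (
    PROPAGATING_RELATIONS,
    OntologyGraph,
    TermNotFoundError,
)
from .taxonomy import TaxonomyTree, in_taxon

__all__ = [
    "ConstraintKind",
    "TaxonConstraint",
    "Annotation",
    "Violation",
    "ViolationReport",
    "SummaryRow",
    "ConstraintIndex",
    "EVIDENCE_CODE_ORDER",
    "ASPECT_ORDER",
    "effective_constraints",
    "check_annotation",
    "check_annotation_set",
    "summarize",
    "gaf_taxon_to_curie",
]

#: The 17 GO evidence codes in report order (16 manual classes then IEA).
EVIDENCE_CODE_ORDER = (
    "EXP", "IDA", "IMP", "IEP", "IPI", "IGI",
    "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
    "TAS", "NAS", "IC", "ND", "IEA",
)

ASPECT_ORDER = ("P", "F", "C")


class ConstraintKind(enum.Enum):
    ONLY_IN = "only_in"
    NEVER_IN = "never_in"


@dataclass(frozen=True)
class TaxonConstraint:
    """One (GO class, kind, taxon-or-union) assertion."""

    go_class: str
    kind: ConstraintKind
    taxon: str

    def sort_key(self) -> tuple[str, str, str]:
        return (self.go_class, self.kind.value, self.taxon)


@dataclass(frozen=True)
class Annotation:
    """One annotation to be checked: gene product G annotated to class A."""

    gene_product: str
    go_class: str
    evidence_code: str
    aspect: str
    taxon: str  # first token of the GAF taxon field, as an NCBITaxon CURIE
    source_line: int = 0
    secondary_taxon: str | None = None  # interaction partner, carried not checked
    symbol: str = ""


@dataclass(frozen=True)
class Violation:
    """An annotation inconsistent with one inherited constraint."""

    annotation: Annotation
    constraint: "TaxonConstraint"
    origin_class: str  # where the constraint is asserted
    path: tuple[str, ...]  # edge path from annotation.go_class to origin_class
    go_name: str = ""


@dataclass
class ViolationReport:
    """Violations plus per-group error/total tallies.

    ``counts`` and ``totals`` are keyed by ``("evidence_code", code)`` and
    ``("aspect", aspect)``; each distinct (annotation, constraint) pair
    counts once.  Problem rows (unknown GO class / unknown taxon /
    obsolete class) are collected aside, never counted as violations.
    Suppressed violations (ignore-listed gene products) are tallied but
    excluded from the violations list.
    """

    violations: list[Violation] = field(default_factory=list)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    totals: dict[tuple[str, str], int] = field(default_factory=dict)
    problems: list[tuple[Annotation, str]] = field(default_factory=list)
    suppressed: list[Violation] = field(default_factory=list)

    @classmethod
    def from_tallies(
        cls,
        group_by: str,
        tallies: dict[str, tuple[int, int]],
    ) -> "ViolationReport":
        """Build a report directly from (errors, total) pairs per group key.

        Used for summary reproduction when only the tallies are known
        (e.g. re-deriving percentage error rates from published counts).
        """
        report = cls()
        for key, (errors, total) in tallies.items():
            report.counts[(group_by, key)] = errors
            report.totals[(group_by, key)] = total
        return report


@dataclass(frozen=True)
class SummaryRow:
    group_key: str
    errors: int
    total: int
    percent: float  # errors/total * 100, half-up to 2 decimals


def gaf_taxon_to_curie(token: str) -> str:
    """Map a GAF taxon token ('taxon:9031') to an NCBITaxon CURIE."""
    if token.startswith("taxon:"):
        return "NCBITaxon:" + token.split(":", 1)[1]
    return token


def _shortest_paths_up(
    go_graph: OntologyGraph, go_class: str
) -> dict[str, tuple[str, ...]]:
    """One shortest propagating path from go_class to each closure member.

    Breadth-first over is_a/part_of/occurs_in edges; among equal-length
    paths the lexicographically smallest parent id wins, so witness paths
    are deterministic.
    """
    go_graph.require(go_class)
    paths: dict[str, tuple[str, ...]] = {go_class: (go_class,)}
    frontier = [go_class]
    while frontier:
        next_frontier: list[str] = []
        for node in sorted(frontier):
            for edge in go_graph.out_edges(node):  # sorted by relation, target
                if edge.relation not in PROPAGATING_RELATIONS:
                    continue
                if edge.object not in paths:
                    paths[edge.object] = paths[node] + (edge.object,)
                    next_frontier.append(edge.object)
        frontier = next_frontier
    return paths


def effective_constraints(
    go_graph: OntologyGraph,
    constraints: list["TaxonConstraint"],
    go_class: str,
) -> list[tuple["TaxonConstraint", tuple[str, ...]]]:
    """All constraints a class inherits, each with a witnessing path.

    A constraint asserted anywhere in the propagation closure of
    ``go_class`` applies to it.  The path is one shortest edge path from
    the class to the constraint's origin (ties broken by id order).
    Result sorted by (origin/kind/taxon) for reproducibility.
    """
    paths = _shortest_paths_up(go_graph, go_class)
    found = [
        (c, paths[c.go_class])
        for c in constraints
        if c.go_class in paths
    ]
    found.sort(key=lambda item: item[0].sort_key())
    return found


class ConstraintIndex:
    """Constraints propagated *down* onto every class they govern.

    The complementary reading of constraint inheritance: instead of
    walking an annotation's class upwards, push each constraint from its
    origin down to all classes whose closure contains the origin, and
    index the result per class.  Violation sets from both routes must
    coincide; the test suite asserts this.
    """

    def __init__(self, go_graph: OntologyGraph, constraints: list["TaxonConstraint"]):
        self.go_graph = go_graph
        dg = go_graph.propagating_digraph()
        self.per_class: dict[str, list[tuple["TaxonConstraint", tuple[str, ...]]]] = {}
        path_cache: dict[str, dict[str, tuple[str, ...]]] = {}
        for constraint in constraints:
            if constraint.go_class not in go_graph:
                raise TermNotFoundError(constraint.go_class)
            # governed set from the *down* direction (who can reach the origin)
            governed = {constraint.go_class} | nx.ancestors(dg, constraint.go_class)
            for cls in governed:
                if cls not in path_cache:
                    path_cache[cls] = _shortest_paths_up(go_graph, cls)
                path = path_cache[cls][constraint.go_class]
                self.per_class.setdefault(cls, []).append((constraint, path))
        for entries in self.per_class.values():
            entries.sort(key=lambda item: item[0].sort_key())

    def check(self, annotation: Annotation, full_tree: TaxonomyTree) -> list[Violation]:
        violations = []
        for constraint, path in self.per_class.get(annotation.go_class, []):
            if _is_violated(constraint, annotation.taxon, full_tree):
                violations.append(
                    Violation(
                        annotation=annotation,
                        constraint=constraint,
                        origin_class=constraint.go_class,
                        path=path,
                        go_name=self.go_graph.terms[annotation.go_class].name,
                    )
                )
        return violations


def _is_violated(
    constraint: "TaxonConstraint", taxon: str, full_tree: TaxonomyTree
) -> bool:
    member = in_taxon(full_tree, taxon, constraint.taxon)
    if constraint.kind is ConstraintKind.ONLY_IN:
        return not member
    return member


def check_annotation(
    annotation: Annotation,
    go_graph: OntologyGraph,
    full_tree: TaxonomyTree,
    constraints: list["TaxonConstraint"],
) -> list[Violation]:
    """All constraints this annotation violates (empty means consistent).

    Every effective only_in constraint whose taxon does not cover the
    annotation's species, and every effective never_in constraint whose
    taxon does, yields one violation — conjunction semantics, so all
    violated constraints are reported, not just the first.  The check
    must run against the full taxonomy: a slim would silently pass
    species added after it was cut.

    Raises :class:`~gotaxon.ontology_model.TermNotFoundError` for an
    unresolved GO class or taxon — an outcome distinct from both pass
    and violation (batch checking collects these as problem rows).
    """
    go_name = go_graph.require(annotation.go_class).name
    full_tree.graph.require(annotation.taxon)
    violations = []
    for constraint, path in effective_constraints(
        go_graph, constraints, annotation.go_class
    ):
        if _is_violated(constraint, annotation.taxon, full_tree):
            violations.append(
                Violation(
                    annotation=annotation,
                    constraint=constraint,
                    origin_class=constraint.go_class,
                    path=path,
                    go_name=go_name,
                )
            )
    return violations


def check_annotation_set(
    rows,
    go_graph: OntologyGraph,
    full_tree: TaxonomyTree,
    constraints: list["TaxonConstraint"],
    ignore_gene_products: set[str] | None = None,
) -> ViolationReport:
    """Check a batch of GAF rows and aggregate tallies.

    Rows become annotations via the first taxon token (the gene product's
    own species; an interaction-partner token is carried along but not
    checked).  Totals and error counts are accumulated per evidence code
    and per aspect.  Rows whose GO class or taxon does not resolve, or
    whose class is obsolete, are collected as problem rows and excluded
    from the tallies.  Gene products on the ignore list have their
    violations moved to the suppressed tally (kept for horizontal-
    transfer cases that curators have chosen to leave flagged but
    unreported).
    """
    ignore = ignore_gene_products or set()
    report = ViolationReport()
    for row in rows:
        taxa = [gaf_taxon_to_curie(t) for t in row.taxon_field]
        annotation = Annotation(
            gene_product=f"{row.db}:{row.db_object_id}",
            go_class=row.go_id,
            evidence_code=row.evidence_code,
            aspect=row.aspect,
            taxon=taxa[0],
            source_line=row.line_number,
            secondary_taxon=taxa[1] if len(taxa) > 1 else None,
            symbol=row.db_object_symbol,
        )
        if annotation.go_class not in go_graph:
            report.problems.append((annotation, f"unknown GO class {annotation.go_class}"))
            continue
        if go_graph.terms[annotation.go_class].obsolete:
            report.problems.append((annotation, f"obsolete GO class {annotation.go_class}"))
            continue
        if annotation.taxon not in full_tree:
            report.problems.append((annotation, f"unknown taxon {annotation.taxon}"))
            continue

        for key in (("evidence_code", annotation.evidence_code),
                    ("aspect", annotation.aspect)):
            report.totals[key] = report.totals.get(key, 0) + 1

        violations = check_annotation(annotation, go_graph, full_tree, constraints)
        suppressed = annotation.gene_product in ignore
        for violation in violations:
            (report.suppressed if suppressed else report.violations).append(violation)
            if not suppressed:
                for key in (("evidence_code", annotation.evidence_code),
                            ("aspect", annotation.aspect)):
                    report.counts[key] = report.counts.get(key, 0) + 1
    return report


def _round_half_up_percent(errors: int, total: int) -> float:
    percent = Decimal(errors) * 100 / Decimal(total)
    return float(percent.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(report: ViolationReport, group_by: str) -> list[SummaryRow]:
    """Per-group error rates, in fixed report order.

    ``group_by`` is ``"evidence_code"`` or ``"aspect"``; rows follow the
    canonical evidence-code order (experimental, computational, author,
    curator, then IEA) or the P/F/C aspect order.  Percent is half-up
    rounded to two decimals.  A group with errors but no recorded total
    is a caller error.
    """
    if group_by == "evidence_code":
        order = EVIDENCE_CODE_ORDER
    elif group_by == "aspect":
        order = ASPECT_ORDER
    else:
        raise ValueError(f"unknown grouping: {group_by!r}")

    keys_present = [
        key for _, key in sorted(
            k for k in set(report.totals) | set(report.counts) if k[0] == group_by
        )
    ]
    rows = []
    ordered = [k for k in order if k in keys_present]
    ordered += [k for k in keys_present if k not in order]
    for key in ordered:
        errors = report.counts.get((group_by, key), 0)
        total = report.totals.get((group_by, key), 0)
        if total <= 0:
            if errors:
                raise ValueError(f"group {key!r} has errors but no total")
            continue
        rows.append(
            SummaryRow(
                group_key=key,
                errors=errors,
                total=total,
                percent=_round_half_up_percent(errors, total),
            )
        )
    return rows
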