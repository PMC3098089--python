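"""Readers and writers: the OBO dialect, GAF 2.0, and report files.

The OBO dialect is the minimal subset the taxon-constraint files need:
``[Term]`` stanzas with id/name/namespace/is_obsolete, ``is_a:`` lines,
``relationship:`` lines (part_of, occurs_in, the regulates family,
only_in_taxon, never_in_taxon) and ``union_of:`` lines on taxon-union
stanzas.  Unknown tag lines are preserved verbatim on the stanza and
re-emitted on write, so round-trips are lossless for tags this tool does
not interpret (synonyms, ranks, xrefs...).

only_in_taxon / never_in_taxon relationship lines are surfaced as
:class:`~gotaxon.checker.TaxonConstraint` records anchored at their
subject stanza rather than as graph edges; a stanza with two or more
``union_of`` lines is surfaced as a :class:`~gotaxon.taxonomy.UnionTaxon`.

GAF 2.0 is the 17-column tab-separated annotation exchange format
(column 7 evidence code, column 9 aspect, column 13 taxon).  GAF 1.0
rows (15 columns) are accepted in permissive mode by padding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .checker import (
    EVIDENCE_CODE_ORDER,
    TaxonConstraint,
    ConstraintKind,
    ViolationReport,
)
from .ontology_model import OntologyGraph, RelationKind, Term
from .taxonomy import TaxonomyTree, UnionTaxon

__all__ = [
    "OboParseError",
    "GafParseError",
    "GafRow",
    "read_obo",
    "write_obo",
    "taxonomy_from_obo",
    "write_taxonomy_obo",
    "read_gaf",
    "write_violations",
    "write_summary",
    "VIOLATION_COLUMNS",
]

_OBO_HEADER = "format-version: 1.2"

_RELATIONSHIP_KEYWORDS = {
    "part_of": RelationKind.PART_OF,
    "occurs_in": RelationKind.OCCURS_IN,
    "regulates": RelationKind.REGULATES_FAMILY,
    "positively_regulates": RelationKind.REGULATES_FAMILY,
    "negatively_regulates": RelationKind.REGULATES_FAMILY,
}

_CONSTRAINT_KEYWORDS = {
    "only_in_taxon": ConstraintKind.ONLY_IN,
    "never_in_taxon": ConstraintKind.NEVER_IN,
}

_KNOWN_TAGS = {"id", "name", "namespace", "is_obsolete", "is_a",
               "relationship", "union_of"}

_TAXON_TOKEN = re.compile(r"taxon:\d+$")

EVIDENCE_CODES = frozenset(EVIDENCE_CODE_ORDER)


class OboParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class GafParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# ---------------------------------------------------------------------------
# OBO dialect
# ---------------------------------------------------------------------------

def read_obo(stream) -> tuple[OntologyGraph, list[TaxonConstraint], list[UnionTaxon]]:
    """Parse the OBO dialect into a graph, constraints and union taxa.

    ``stream`` is an iterable of lines (an open text file or a list).
    Raises :class:`OboParseError` with the offending line number for a
    stanza without an id, an unknown relationship keyword, or a union
    stanza with fewer than two members.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()

    graph = OntologyGraph()
    constraints: list[TaxonConstraint] = []
    unions: list[UnionTaxon] = []

    stanza: list[tuple[int, str]] | None = None
    stanza_start = 0

    def flush() -> None:
        nonlocal stanza
        if stanza is None:
            return
        term_id: str | None = None
        name = ""
        namespace = ""
        obsolete = False
        extras: list[str] = []
        is_a_targets: list[str] = []
        rel_lines: list[tuple[RelationKind, str]] = []
        constraint_lines: list[tuple[ConstraintKind, str]] = []
        union_members: list[str] = []

        for lineno, line in stanza:
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                term_id = value
            elif tag == "name":
                name = value
            elif tag == "namespace":
                namespace = value
            elif tag == "is_obsolete":
                obsolete = value.lower() == "true"
            elif tag == "is_a":
                is_a_targets.append(value.split("!")[0].strip())
            elif tag == "union_of":
                union_members.append(value.split("!")[0].strip())
            elif tag == "relationship":
                parts = value.split("!")[0].split()
                if len(parts) != 2:
                    raise OboParseError(f"malformed relationship line: {line!r}", lineno)
                keyword, target = parts
                if keyword in _RELATIONSHIP_KEYWORDS:
                    rel_lines.append((_RELATIONSHIP_KEYWORDS[keyword], target))
                elif keyword in _CONSTRAINT_KEYWORDS:
                    constraint_lines.append((_CONSTRAINT_KEYWORDS[keyword], target))
                else:
                    raise OboParseError(f"unknown relationship keyword {keyword!r}", lineno)
            else:
                extras.append(line)

        if term_id is None:
            raise OboParseError("stanza missing id", stanza_start)
        if len(union_members) == 1:
            raise OboParseError(
                f"union stanza {term_id} has fewer than 2 members", stanza_start
            )

        graph.add_term(
            Term(id=term_id, name=name, namespace=namespace,
                 obsolete=obsolete, extras=tuple(extras))
        )
        for target in is_a_targets:
            graph.add_edge(term_id, RelationKind.IS_A, target)
        for relation, target in rel_lines:
            graph.add_edge(term_id, relation, target)
        for kind, target in constraint_lines:
            constraints.append(TaxonConstraint(term_id, kind, target))
        if union_members:
            unions.append(UnionTaxon(term_id, tuple(union_members)))
        stanza = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped == "[Term]":
            flush()
            stanza = []
            stanza_start = lineno
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            flush()  # other stanza types (e.g. [Typedef]) are skipped
            stanza = None
            continue
        if stanza is not None and stripped:
            stanza.append((lineno, stripped))
    flush()

    constraints.sort(key=TaxonConstraint.sort_key)
    unions.sort(key=lambda u: u.id)
    return graph, constraints, unions


def write_obo(
    graph: OntologyGraph,
    constraints: list[TaxonConstraint] = (),
    unions: list[UnionTaxon] = (),
    stream=None,
) -> str | None:
    """Emit the OBO dialect, stanzas sorted by id.

    ``read_obo(write_obo(x))`` reconstructs the in-memory objects exactly
    (the regulates sub-relations are normalised to ``regulates``).  If
    ``stream`` is None the document is returned as a string.
    """
    by_origin: dict[str, list[TaxonConstraint]] = {}
    for c in sorted(constraints, key=TaxonConstraint.sort_key):
        by_origin.setdefault(c.go_class, []).append(c)
    union_by_id = {u.id: u for u in unions}

    lines: list[str] = [_OBO_HEADER, ""]
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        edges = graph.out_edges(term_id)
        for edge in edges:
            if edge.relation is RelationKind.IS_A:
                lines.append(f"is_a: {edge.object}")
        for edge in edges:
            if edge.relation in (RelationKind.PART_OF, RelationKind.OCCURS_IN,
                                 RelationKind.REGULATES_FAMILY):
                lines.append(f"relationship: {edge.relation.value} {edge.object}")
        for c in by_origin.get(term_id, ()):
            keyword = "only_in_taxon" if c.kind is ConstraintKind.ONLY_IN else "never_in_taxon"
            lines.append(f"relationship: {keyword} {c.taxon}")
        if term_id in union_by_id:
            for member in union_by_id[term_id].members:
                lines.append(f"union_of: {member}")
        lines.extend(term.extras)
        lines.append("")

    # unions whose term is not declared in this graph still get a stanza,
    # so a union list is never silently dropped on write
    for union_id in sorted(set(union_by_id) - set(graph.terms)):
        lines.append("[Term]")
        lines.append(f"id: {union_id}")
        for member in union_by_id[union_id].members:
            lines.append(f"union_of: {member}")
        lines.append("")

    text = "\n".join(lines)
    if stream is None:
        return text
    stream.write(text)
    return None


def taxonomy_from_obo(stream) -> tuple[TaxonomyTree, list[UnionTaxon]]:
    """Read a taxonomy OBO file into a tree plus its union terms.

    ``synonym:`` and ``property_value: has_rank`` lines, preserved as
    stanza extras by :func:`read_obo`, are lifted into the tree's
    synonym/rank maps.
    """
    graph, constraints, unions = read_obo(stream)
    if constraints:
        raise OboParseError("taxonomy file carries taxon constraints", 0)
    rank: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for term in graph.terms.values():
        for line in term.extras:
            tag, _, value = line.partition(":")
            value = value.strip()
            if tag == "property_value" and value.startswith("has_rank "):
                rank[term.id] = value.split(" ", 1)[1].strip().strip('"')
            elif tag == "synonym":
                m = re.match(r'"([^"]*)"', value)
                if m:
                    synonyms.setdefault(term.id, []).append(m.group(1))
    return TaxonomyTree(graph=graph, rank=rank, synonyms=synonyms), unions


def write_taxonomy_obo(tree: TaxonomyTree, unions: list[UnionTaxon] = (), stream=None):
    """Emit a taxonomy tree, folding rank/synonyms back into stanza extras."""
    graph = tree.graph.copy()
    for term_id in sorted(graph.terms):
        extras = list(graph.terms[term_id].extras)
        for syn in tree.synonyms.get(term_id, ()):
            line = f'synonym: "{syn}" RELATED []'
            if line not in extras:
                extras.append(line)
        if term_id in tree.rank:
            line = f'property_value: has_rank "{tree.rank[term_id]}"'
            if line not in extras:
                extras.append(line)
        graph.rename(term_id, extras=tuple(extras))
    return write_obo(graph, [], list(unions), stream)


# ---------------------------------------------------------------------------
# GAF 2.0
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GafRow:
    """One GAF data row (GAF 2.0: 17 tab-separated columns)."""

    db: str
    db_object_id: str
    db_object_symbol: str
    qualifier: str
    go_id: str
    reference: str
    evidence_code: str
    aspect: str
    taxon_field: tuple[str, ...]  # 1 or 2 "taxon:<digits>" tokens
    extra_columns: tuple[str, ...] = ()
    line_number: int = 0


_GAF_MANDATORY = {0: "db", 1: "db_object_id", 2: "db_object_symbol",
                  4: "go_id", 6: "evidence_code", 8: "aspect", 12: "taxon"}


def _parse_gaf_line(cols: list[str], lineno: int) -> GafRow:
    for index, label in _GAF_MANDATORY.items():
        if not cols[index].strip():
            raise GafParseError(f"empty mandatory column {label}", lineno)
    evidence = cols[6].strip()
    if evidence not in EVIDENCE_CODES:
        raise GafParseError(f"unknown evidence code {evidence!r}", lineno)
    aspect = cols[8].strip()
    if aspect not in ("P", "F", "C"):
        raise GafParseError(f"unknown aspect {aspect!r}", lineno)
    tokens = tuple(t.strip() for t in cols[12].split("|") if t.strip())
    if not tokens or any(not _TAXON_TOKEN.match(t) for t in tokens):
        raise GafParseError(f"malformed taxon field {cols[12]!r}", lineno)
    return GafRow(
        db=cols[0], db_object_id=cols[1], db_object_symbol=cols[2],
        qualifier=cols[3], go_id=cols[4], reference=cols[5],
        evidence_code=evidence, aspect=aspect, taxon_field=tokens,
        extra_columns=tuple(cols[7:8] + cols[9:12] + cols[13:]),
        line_number=lineno,
    )


def read_gaf(stream, strict: bool = True):
    """Parse GAF text into rows; '!' comment lines and blanks are skipped.

    In strict mode (default) returns ``list[GafRow]`` and raises
    :class:`GafParseError` naming the first bad line.  In permissive mode
    returns ``(rows, errors)`` where errors are the collected
    :class:`GafParseError` instances; 15-column GAF 1.0 rows are padded
    to 17 columns instead of rejected.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    rows: list[GafRow] = []
    errors: list[GafParseError] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        try:
            if len(cols) == 15 and not strict:  # GAF 1.0: pad the two 2.0 columns
                cols = cols + ["", ""]
            if len(cols) != 17:
                raise GafParseError(
                    f"expected 17 columns, found {len(cols)}", lineno
                )
            rows.append(_parse_gaf_line(cols, lineno))
        except GafParseError as exc:
            if strict:
                raise
            errors.append(exc)
    if strict:
        return rows
    return rows, errors


# ---------------------------------------------------------------------------
# Violation / summary reports
# ---------------------------------------------------------------------------

VIOLATION_COLUMNS = (
    "db", "db_object_id", "db_object_symbol", "go_id", "go_name",
    "evidence_code", "aspect", "taxon", "constraint_kind",
    "constraint_taxon", "constraint_origin_class", "inheritance_path",
)


def write_violations(report: ViolationReport, stream=None) -> str | None:
    """Emit the violations file: one tab-separated row per violation.

    Rows keep GAF file order (source line) and then constraint identity,
    so re-running on identical inputs yields identical bytes.  Suppressed
    (ignore-listed) violations are not written.
    """
    lines = ["\t".join(VIOLATION_COLUMNS)]
    ordered = sorted(
        report.violations,
        key=lambda v: (v.annotation.source_line, v.constraint.sort_key()),
    )
    for v in ordered:
        ann = v.annotation
        db, _, obj = ann.gene_product.partition(":")
        lines.append("\t".join((
            db, obj, ann.symbol, ann.go_class, v.go_name,
            ann.evidence_code, ann.aspect, ann.taxon,
            v.constraint.kind.value, v.constraint.taxon,
            v.origin_class, ">".join(v.path),
        )))
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


def write_summary(rows, stream=None) -> str | None:
    """Emit summary rows (group, errors, total, percent) as TSV."""
    lines = ["group\terrors\ttotal\tpercent"]
    for row in rows:
        lines.append(f"{row.group_key}\t{row.errors}\t{row.total}\t{row.percent:.2f}")
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None
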