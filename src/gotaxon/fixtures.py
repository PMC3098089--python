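"""Deterministic generators for every input the checker consumes.

Two generators live here.

:func:`paper_fixture` hand-builds the worked examples that motivate the
system: the lactation branch restricted to Mammalia, photosynthesis
restricted to the four-clade union "Viridiplantae or Bacteria or
Euglenozoa or Archaea" with the C4 sub-type narrowed to Viridiplantae,
secretory granule barred from Ascomycota, spindle pole body organization
restricted to Fungi, and nucleus constraints inherited by nuclear
translation through occurs_in.  Real NCBI and GO identifiers are used
where they are standard; the 'nuclear translation' id (GO:0099999) and
the exact taxonomy topology beyond the named clades are fixture
inventions.  The bundled GAF mixes passing and violating rows and the
expected violation list is the hand-checked oracle.

:func:`random_instance` produces seeded random ontologies, taxonomies,
constraints and annotations with *planted* violations.  Ground truth is
labelled by :func:`brute_force_violations`, an independent full-path-
enumeration checker kept deliberately naive so the production checker
can be validated against it.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from pathlib import Path

from .checker import ConstraintKind, TaxonConstraint
from .io_formats import (
    GafRow,
    read_gaf,
    write_obo,
    write_taxonomy_obo,
)
from .ontology_model import OntologyGraph, RelationKind, Term
from .taxonomy import TaxonomyTree, UnionTaxon, materialize_unions

__all__ = [
    "PaperFixture",
    "RandomInstance",
    "paper_fixture",
    "random_instance",
    "brute_force_violations",
    "write_fixture_files",
]


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def brute_force_violations(
    go_graph: OntologyGraph,
    tree: TaxonomyTree,
    constraints: list[TaxonConstraint],
    go_class: str,
    taxon: str,
) -> list[TaxonConstraint]:
    """Violated constraints for one (class, taxon) pair, the slow way.

    Enumerates every simple path upward from ``go_class`` over
    is_a/part_of/occurs_in edges to find the reachable class set, and
    walks raw is_a edges to find the taxon's ancestors.  Shares no code
    with the production checker beyond the data model.
    """
    reachable: set[str] = set()

    def walk(node: str, on_path: set[str]) -> None:
        reachable.add(node)
        for edge in go_graph.out_edges(node):
            if edge.relation.value not in ("is_a", "part_of", "occurs_in"):
                continue
            if edge.object in on_path:
                continue
            walk(edge.object, on_path | {edge.object})

    walk(go_class, {go_class})

    taxon_ancestors: set[str] = set()
    frontier = [taxon]
    while frontier:
        node = frontier.pop()
        if node in taxon_ancestors:
            continue
        taxon_ancestors.add(node)
        for edge in tree.graph.out_edges(node):
            if edge.relation.value == "is_a":
                frontier.append(edge.object)

    violated = []
    for constraint in constraints:
        if constraint.go_class not in reachable:
            continue
        member = constraint.taxon in taxon_ancestors
        if constraint.kind is ConstraintKind.ONLY_IN and not member:
            violated.append(constraint)
        elif constraint.kind is ConstraintKind.NEVER_IN and member:
            violated.append(constraint)
    violated.sort(key=TaxonConstraint.sort_key)
    return violated


# ---------------------------------------------------------------------------
# the worked-example fixture
# ---------------------------------------------------------------------------

@dataclass
class PaperFixture:
    go_graph: OntologyGraph
    full_tree: TaxonomyTree  # unions materialized; always check against this
    tree: TaxonomyTree  # the plain taxonomy as read from file
    constraints: list[TaxonConstraint]
    unions: list[UnionTaxon]
    gaf_rows: list[GafRow]
    gaf_text: str
    #: (gene_product, go_id, origin_class, kind value, constraint taxon)
    expected_violations: list[tuple[str, str, str, str, str]]


_GO_TERMS = [
    # (id, name, namespace, [(relation, parent), ...])
    ("GO:0008150", "biological_process", "biological_process", []),
    ("GO:0048856", "anatomical structure development", "biological_process",
     [("is_a", "GO:0008150")]),
    ("GO:0030879", "mammary gland development", "biological_process",
     [("is_a", "GO:0048856")]),
    ("GO:0007595", "lactation", "biological_process",
     [("is_a", "GO:0030879")]),
    ("GO:0050789", "regulation of biological process", "biological_process",
     [("is_a", "GO:0008150")]),
    ("GO:1903487", "regulation of lactation", "biological_process",
     [("is_a", "GO:0050789"), ("regulates", "GO:0007595")]),
    ("GO:0008152", "metabolic process", "biological_process",
     [("is_a", "GO:0008150")]),
    ("GO:0015979", "photosynthesis", "biological_process",
     [("is_a", "GO:0008152")]),
    ("GO:0019684", "photosynthesis, light reaction", "biological_process",
     [("part_of", "GO:0015979")]),
    ("GO:0009760", "C4 photosynthesis", "biological_process",
     [("is_a", "GO:0015979")]),
    ("GO:0009762", "PEP carboxykinase C4 photosynthesis", "biological_process",
     [("is_a", "GO:0009760")]),
    ("GO:0006412", "translation", "biological_process",
     [("is_a", "GO:0008152")]),
    # fixture-invented id: an experimental-extension style process that
    # occurs in the nucleus and therefore inherits its constraints
    ("GO:0099999", "nuclear translation", "biological_process",
     [("is_a", "GO:0006412"), ("occurs_in", "GO:0005634")]),
    ("GO:0006996", "organelle organization", "biological_process",
     [("is_a", "GO:0008150")]),
    ("GO:0051300", "spindle pole body organization", "biological_process",
     [("is_a", "GO:0006996")]),
    ("GO:0005575", "cellular_component", "cellular_component", []),
    ("GO:0043226", "organelle", "cellular_component",
     [("is_a", "GO:0005575")]),
    ("GO:0043231", "intracellular membrane-bounded organelle", "cellular_component",
     [("is_a", "GO:0043226")]),
    ("GO:0005634", "nucleus", "cellular_component",
     [("is_a", "GO:0043231")]),
    ("GO:0031410", "cytoplasmic vesicle", "cellular_component",
     [("is_a", "GO:0043226")]),
    ("GO:0030141", "secretory granule", "cellular_component",
     [("is_a", "GO:0031410")]),
]

_TAXA = [
    # (id, name, parent or None)
    ("NCBITaxon:1", "root", None),
    ("NCBITaxon:131567", "cellular organisms", "NCBITaxon:1"),
    ("NCBITaxon:2", "Bacteria", "NCBITaxon:131567"),
    ("NCBITaxon:2157", "Archaea", "NCBITaxon:131567"),
    ("NCBITaxon:2759", "Eukaryota", "NCBITaxon:131567"),
    ("NCBITaxon:562", "Escherichia coli", "NCBITaxon:2"),
    ("NCBITaxon:33090", "Viridiplantae", "NCBITaxon:2759"),
    ("NCBITaxon:3702", "Arabidopsis thaliana", "NCBITaxon:33090"),
    ("NCBITaxon:33682", "Euglenozoa", "NCBITaxon:2759"),
    ("NCBITaxon:3039", "Euglena gracilis", "NCBITaxon:33682"),
    ("NCBITaxon:4751", "Fungi", "NCBITaxon:2759"),
    ("NCBITaxon:4890", "Ascomycota", "NCBITaxon:4751"),
    ("NCBITaxon:4932", "Saccharomyces cerevisiae", "NCBITaxon:4890"),
    ("NCBITaxon:4896", "Schizosaccharomyces pombe", "NCBITaxon:4890"),
    ("NCBITaxon:5204", "Basidiomycota", "NCBITaxon:4751"),
    ("NCBITaxon:5270", "Ustilago maydis", "NCBITaxon:5204"),
    ("NCBITaxon:33208", "Metazoa", "NCBITaxon:2759"),
    ("NCBITaxon:7227", "Drosophila melanogaster", "NCBITaxon:33208"),
    ("NCBITaxon:8782", "Aves", "NCBITaxon:33208"),
    ("NCBITaxon:9031", "Gallus gallus", "NCBITaxon:8782"),
    ("NCBITaxon:40674", "Mammalia", "NCBITaxon:33208"),
    ("NCBITaxon:9258", "Ornithorhynchus anatinus", "NCBITaxon:40674"),
    ("NCBITaxon:32525", "Theria", "NCBITaxon:40674"),
    ("NCBITaxon:568129", "Desmalopex leucopterus", "NCBITaxon:32525"),
]

_UNION_ID = "NCBITaxon_Union:0000021"

_CONSTRAINTS = [
    ("GO:0030879", ConstraintKind.ONLY_IN, "NCBITaxon:40674"),   # Mammalia
    ("GO:0015979", ConstraintKind.ONLY_IN, _UNION_ID),           # photosynthesis union
    ("GO:0009760", ConstraintKind.ONLY_IN, "NCBITaxon:33090"),   # Viridiplantae
    ("GO:0030141", ConstraintKind.NEVER_IN, "NCBITaxon:4890"),   # Ascomycota
    ("GO:0051300", ConstraintKind.ONLY_IN, "NCBITaxon:4751"),    # Fungi
    ("GO:0005634", ConstraintKind.ONLY_IN, "NCBITaxon:2759"),    # Eukaryota
]

# (db, object id, symbol, go id, evidence, aspect, taxon token)
_GAF_SPEC = [
    ("UniProtKB", "P00001", "chick1", "GO:0007595", "IEA", "P", "taxon:9031"),
    ("UniProtKB", "P00002", "platy1", "GO:0007595", "IDA", "P", "taxon:9258"),
    ("UniProtKB", "P00003", "chick2", "GO:1903487", "IEA", "P", "taxon:9031"),
    ("UniProtKB", "P00004", "fly1", "GO:0019684", "IEA", "P", "taxon:7227"),
    ("TAIR", "AT1G01", "psb1", "GO:0015979", "IDA", "P", "taxon:3702"),
    ("UniProtKB", "P00005", "eug1", "GO:0009762", "ISS", "P", "taxon:3039"),
    ("TAIR", "AT1G02", "pck1", "GO:0009762", "IMP", "P", "taxon:3702"),
    ("SGD", "S000001", "sec1", "GO:0030141", "IDA", "C", "taxon:4932"),
    ("UniProtKB", "P00006", "ust1", "GO:0030141", "ISS", "C", "taxon:5270"),
    ("PomBase", "SPAC1", "spb1", "GO:0051300", "IMP", "P", "taxon:4896"),
    ("EcoCyc", "EG10001", "ecn1", "GO:0099999", "IEA", "P", "taxon:562"),
    ("UniProtKB", "P00007", "bat1", "GO:0030879", "ISS", "P", "taxon:568129"),
]

#: (gene_product, go_id, origin_class, kind, constraint taxon)
_EXPECTED_VIOLATIONS = [
    # chicken annotated to lactation: fails the Mammalia restriction that
    # lactation inherits from mammary gland development
    ("UniProtKB:P00001", "GO:0007595", "GO:0030879", "only_in", "NCBITaxon:40674"),
    # Drosophila to 'photosynthesis, light reaction': fails the four-way
    # union restriction inherited from photosynthesis through part_of
    ("UniProtKB:P00004", "GO:0019684", "GO:0015979", "only_in", _UNION_ID),
    # Euglena to the PEP carboxykinase C4 sub-type: passes the union but
    # fails the narrower Viridiplantae restriction
    ("UniProtKB:P00005", "GO:0009762", "GO:0009760", "only_in", "NCBITaxon:33090"),
    # baker's yeast to secretory granule: hits the Ascomycota exclusion
    ("SGD:S000001", "GO:0030141", "GO:0030141", "never_in", "NCBITaxon:4890"),
    # E. coli to nuclear translation: inherits the eukaryote-only nucleus
    # restriction through occurs_in
    ("EcoCyc:EG10001", "GO:0099999", "GO:0005634", "only_in", "NCBITaxon:2759"),
]


def _gaf_line(db, obj, symbol, go_id, evidence, aspect, taxon) -> str:
    cols = [db, obj, symbol, "", go_id, "GO_REF:0000001", evidence, "",
            aspect, "", "", "protein", taxon, "20100101", db, "", ""]
    return "\t".join(cols)


def paper_fixture() -> PaperFixture:
    """The hand-built worked-example fixture with its violation oracle."""
    go_graph = OntologyGraph()
    for term_id, name, namespace, _parents in _GO_TERMS:
        go_graph.add_term(Term(id=term_id, name=name, namespace=namespace))
    for term_id, _name, _namespace, parents in _GO_TERMS:
        for relation, parent in parents:
            go_graph.add_edge(term_id, RelationKind(relation), parent)

    tax_graph = OntologyGraph()
    for taxon_id, name, _parent in _TAXA:
        tax_graph.add_term(Term(id=taxon_id, name=name, namespace="taxonomy"))
    tax_graph.add_term(
        Term(id=_UNION_ID,
             name="Viridiplantae or Bacteria or Euglenozoa or Archaea",
             namespace="taxonomy")
    )
    for taxon_id, _name, parent in _TAXA:
        if parent is not None:
            tax_graph.add_edge(taxon_id, RelationKind.IS_A, parent)
    tree = TaxonomyTree(graph=tax_graph)

    unions = [
        UnionTaxon(
            _UNION_ID,
            ("NCBITaxon:33090", "NCBITaxon:2", "NCBITaxon:33682", "NCBITaxon:2157"),
        )
    ]
    full_tree = materialize_unions(tree, unions)

    constraints = sorted(
        (TaxonConstraint(cls, kind, taxon) for cls, kind, taxon in _CONSTRAINTS),
        key=TaxonConstraint.sort_key,
    )

    gaf_lines = ["!gaf-version: 2.0"]
    gaf_lines += [_gaf_line(*row) for row in _GAF_SPEC]
    gaf_text = "\n".join(gaf_lines) + "\n"
    gaf_rows = read_gaf(gaf_text)

    return PaperFixture(
        go_graph=go_graph,
        full_tree=full_tree,
        tree=tree,
        constraints=constraints,
        unions=unions,
        gaf_rows=gaf_rows,
        gaf_text=gaf_text,
        expected_violations=list(_EXPECTED_VIOLATIONS),
    )


# ---------------------------------------------------------------------------
# seeded random instances with planted violations
# ---------------------------------------------------------------------------

@dataclass
class RandomInstance:
    go_graph: OntologyGraph
    tree: TaxonomyTree
    constraints: list[TaxonConstraint]
    gaf_rows: list[GafRow]
    gaf_text: str
    #: ground truth: (gaf line number, violated constraint), one entry per
    #: (annotation, constraint) pair, labelled by the brute-force oracle
    plant_list: list[tuple[int, TaxonConstraint]]

    def sha256(self) -> str:
        """Digest of the serialized instance, for determinism checks."""
        payload = write_obo(self.go_graph, self.constraints, [])
        payload += write_obo(self.tree.graph, [], [])
        payload += self.gaf_text
        payload += repr(self.plant_list)
        return hashlib.sha256(payload.encode()).hexdigest()


_RELATION_WEIGHTS = [
    (RelationKind.IS_A, 0.7),
    (RelationKind.PART_OF, 0.2),
    (RelationKind.OCCURS_IN, 0.1),
]

_EVIDENCE_POOL = ("IEA", "IDA", "IMP", "ISS", "TAS", "EXP")


class InstanceGenerationError(RuntimeError):
    """Raised when the requested instance is infeasible within retry bounds."""


def _weighted_relation(rng: random.Random) -> RelationKind:
    roll = rng.random()
    acc = 0.0
    for relation, weight in _RELATION_WEIGHTS:
        acc += weight
        if roll < acc:
            return relation
    return RelationKind.OCCURS_IN


def random_instance(
    seed: int,
    n_go_terms: int = 30,
    n_taxa: int = 20,
    n_constraints: int = 5,
    n_annotations: int = 50,
    violation_rate: float = 0.2,
) -> RandomInstance:
    """A seeded random checking problem with known ground truth.

    The GO side is a random DAG: term i > 0 gets one to three parents
    among earlier terms, with relation drawn is_a 0.7 / part_of 0.2 /
    occurs_in 0.1.  The taxonomy is a random rooted tree whose leaves are
    the species pool.  Constraints are placed on non-leaf GO terms with
    non-leaf taxa.  Each annotation is drawn uniformly from the violating
    (class, species) pairs with probability ``violation_rate`` and from
    the clean pairs otherwise; every row is then labelled by the
    brute-force oracle, so ``plant_list`` is exact even when a planted
    row trips several constraints at once.  Identical seeds give
    byte-identical instances; an instance whose constraints leave no
    feasible pair of the requested kind raises
    :class:`InstanceGenerationError`.
    """
    if not 0.0 <= violation_rate <= 1.0:
        raise ValueError("violation_rate must be within [0, 1]")
    rng = random.Random(seed)

    go_graph = OntologyGraph()
    go_ids = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    for i, term_id in enumerate(go_ids):
        go_graph.add_term(Term(id=term_id, name=f"term {i + 1}",
                               namespace="biological_process"))
        if i == 0:
            continue
        n_parents = min(rng.randint(1, 3), i)
        for parent in rng.sample(go_ids[:i], n_parents):
            go_graph.add_edge(term_id, _weighted_relation(rng), parent)

    tax_graph = OntologyGraph()
    tax_ids = [f"NCBITaxon:{9000000 + i}" for i in range(1, n_taxa + 1)]
    parent_of: dict[str, str] = {}
    for i, taxon_id in enumerate(tax_ids):
        tax_graph.add_term(Term(id=taxon_id, name=f"taxon {i + 1}",
                                namespace="taxonomy"))
        if i == 0:
            continue
        parent = rng.choice(tax_ids[:i])
        parent_of[taxon_id] = parent
        tax_graph.add_edge(taxon_id, RelationKind.IS_A, parent)
    tree = TaxonomyTree(graph=tax_graph)

    species = sorted(set(tax_ids) - set(parent_of.values()))
    internal_taxa = sorted(set(parent_of.values()))
    go_leaves = {e.subject for e in go_graph.edges} - {e.object for e in go_graph.edges}
    internal_go = sorted(set(go_ids) - go_leaves) or go_ids

    constraints: list[TaxonConstraint] = []
    seen = set()
    for _ in range(n_constraints * 10):
        if len(constraints) >= n_constraints:
            break
        cls = rng.choice(internal_go)
        taxon = rng.choice(internal_taxa)
        kind = rng.choice((ConstraintKind.ONLY_IN, ConstraintKind.NEVER_IN))
        key = (cls, kind, taxon)
        if key in seen:
            continue
        seen.add(key)
        constraints.append(TaxonConstraint(cls, kind, taxon))
    constraints.sort(key=TaxonConstraint.sort_key)

    # Feasible (class, species) pairs for each row kind, enumerated once.
    # Drawing uniformly from the enumerated set equals rejection sampling
    # but cannot miss rare feasible pairs; a genuinely empty set (e.g. a
    # root-level constraint leaving no clean pair) is an error.
    clean_pairs: list[tuple[str, str]] = []
    violating_pairs: list[tuple[str, str]] = []
    for cls in go_ids:
        for taxon in species:
            if brute_force_violations(go_graph, tree, constraints, cls, taxon):
                violating_pairs.append((cls, taxon))
            else:
                clean_pairs.append((cls, taxon))

    rows_spec: list[tuple[str, str, list[TaxonConstraint]]] = []
    for i in range(n_annotations):
        want_violation = rng.random() < violation_rate
        pool = violating_pairs if want_violation else clean_pairs
        if not pool:
            raise InstanceGenerationError(
                f"no feasible {'violating' if want_violation else 'clean'} "
                f"(class, species) pair exists for annotation {i}"
            )
        cls, taxon = rng.choice(pool)
        truth = brute_force_violations(go_graph, tree, constraints, cls, taxon)
        rows_spec.append((cls, taxon, truth))

    gaf_lines = ["!gaf-version: 2.0"]
    plant_list: list[tuple[int, TaxonConstraint]] = []
    for i, (cls, taxon, truth) in enumerate(rows_spec):
        line_number = len(gaf_lines) + 1
        gaf_lines.append(_gaf_line(
            "FIXDB", f"OBJ{i:05d}", f"g{i}", cls,
            rng.choice(_EVIDENCE_POOL), rng.choice("PFC"),
            "taxon:" + taxon.split(":")[1],
        ))
        for constraint in truth:
            plant_list.append((line_number, constraint))
    gaf_text = "\n".join(gaf_lines) + "\n"

    return RandomInstance(
        go_graph=go_graph,
        tree=tree,
        constraints=constraints,
        gaf_rows=read_gaf(gaf_text),
        gaf_text=gaf_text,
        plant_list=plant_list,
    )


def _reachable(graph: OntologyGraph, start: str) -> set[str]:
    out = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for edge in graph.out_edges(node):
            if edge.relation.value in ("is_a", "part_of", "occurs_in"):
                if edge.object not in out:
                    out.add(edge.object)
                    stack.append(edge.object)
    return out


# ---------------------------------------------------------------------------
# fixture files on disk
# ---------------------------------------------------------------------------

def write_fixture_files(directory: str | Path, instance=None) -> dict[str, Path]:
    """Write fixture input files (OBO/GAF dialects) under ``directory``.

    With no ``instance`` the worked-example fixture is written; pass a
    :class:`RandomInstance` to dump a generated one.  Returns the paths
    keyed by role (go, taxonomy, triggers, gaf).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if instance is None:
        fx = paper_fixture()
        go_graph, tree, unions = fx.go_graph, fx.tree, fx.unions
        constraints, gaf_text = fx.constraints, fx.gaf_text
    else:
        go_graph, tree, unions = instance.go_graph, instance.tree, []
        constraints, gaf_text = instance.constraints, instance.gaf_text

    triggers_graph = OntologyGraph()
    for constraint in constraints:
        if constraint.go_class not in triggers_graph:
            term = go_graph.terms[constraint.go_class]
            triggers_graph.add_term(Term(id=term.id, name=term.name,
                                         namespace=term.namespace))

    paths = {
        "go": directory / "go.obo",
        "taxonomy": directory / "taxonomy.obo",
        "triggers": directory / "taxon_go_triggers.obo",
        "gaf": directory / "annotations.gaf",
    }
    paths["go"].write_text(write_obo(go_graph, [], []))
    paths["taxonomy"].write_text(write_taxonomy_obo(tree, unions))
    paths["triggers"].write_text(write_obo(triggers_graph, constraints, []))
    paths["gaf"].write_text(gaf_text)
    return paths
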