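"""Taxonomy-side reasoning: in_taxon closure, unions, LCAs and slims.

The taxonomy is an ontology graph whose only propagating relation is
``is_a`` and whose non-union part is a rooted tree (every non-root taxon
has exactly one parent).  Union taxa — named disjunctions such as
"Viridiplantae or Bacteria or Euglenozoa or Archaea" — exist because
some biological capabilities span clades with no common NCBI superclass.
A union is materialised by adding one ``is_a`` edge from each member
into the union term, after which a single reflexive-transitive closure
algorithm answers membership for plain taxa and unions alike.

The slim generator reduces the full taxonomy (hundreds of thousands of
classes in production) to the annotated species plus every pairwise
least common ancestor, for human-guided constraint editing.  Checking
must always use the *full* tree: species added to annotation sets after
the slim was cut would otherwise silently escape their constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .ontology_model import (
    OntologyGraph,
    RelationKind,
    Term,
    TermNotFoundError,
)

__all__ = [
    "UnionTaxon",
    "TaxonomyTree",
    "materialize_unions",
    "in_taxon",
    "lca",
    "build_slim",
    "read_ncbi_dump",
]

UNION_PREFIX = "NCBITaxon_Union:"


@dataclass(frozen=True)
class UnionTaxon:
    """A named disjunction of taxonomy classes.

    Members must be distinct existing taxa, none an ancestor of another
    (a redundant member would collapse the union onto it).
    """

    id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"union {self.id} needs >=2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"union {self.id} has duplicate members")


@dataclass
class TaxonomyTree:
    """An ontology graph constrained to taxonomy shape, plus NCBI metadata."""

    graph: OntologyGraph
    rank: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.graph

    @staticmethod
    def is_union(taxon_id: str) -> bool:
        return taxon_id.startswith(UNION_PREFIX)

    def parent(self, taxon_id: str) -> str | None:
        """The single non-union is_a parent, or None for roots/unions."""
        self.graph.require(taxon_id)
        parents = [
            e.object
            for e in self.graph.out_edges(taxon_id)
            if e.relation is RelationKind.IS_A and not self.is_union(e.object)
        ]
        if len(parents) > 1:
            raise ValueError(f"taxon {taxon_id} has multiple parents: {parents}")
        return parents[0] if parents else None

    def ancestors_or_self(self, taxon_id: str) -> set[str]:
        """Reflexive is_a closure, including any materialised unions."""
        self.graph.require(taxon_id)
        closure: set[str] = set()
        stack = [taxon_id]
        while stack:
            node = stack.pop()
            if node in closure:
                continue
            closure.add(node)
            for edge in self.graph.out_edges(node):
                if edge.relation is RelationKind.IS_A:
                    stack.append(edge.object)
        return closure

    def chain_to_root(self, taxon_id: str) -> list[str]:
        """[taxon, parent, ..., root] along the unique tree path."""
        chain = [taxon_id]
        seen = {taxon_id}
        while True:
            up = self.parent(chain[-1])
            if up is None:
                return chain
            if up in seen:
                raise ValueError(f"cycle in taxonomy at {up}")
            seen.add(up)
            chain.append(up)

    def leaves(self) -> set[str]:
        non_union = {t for t in self.graph.terms if not self.is_union(t)}
        parents = {
            e.object
            for e in self.graph.iter_edges(RelationKind.IS_A)
            if not self.is_union(e.object)
        }
        return non_union - parents

    def copy(self) -> "TaxonomyTree":
        return TaxonomyTree(
            graph=self.graph.copy(),
            rank=dict(self.rank),
            synonyms={k: list(v) for k, v in self.synonyms.items()},
        )


def materialize_unions(
    tree: TaxonomyTree, unions: list[UnionTaxon]
) -> TaxonomyTree:
    """Return a copy of the tree with member->union is_a edges added.

    Each union term is declared (if absent) and every member Ti gains the
    edge ``Ti is_a U``, after which plain closure answers union
    membership.  The input tree is untouched.
    """
    out = tree.copy()
    for union in sorted(unions, key=lambda u: u.id):
        for member in union.members:
            if member not in out.graph:
                raise TermNotFoundError(member)
        if union.id not in out.graph:
            out.graph.add_term(Term(id=union.id, namespace="taxonomy"))
        for member in union.members:
            out.graph.add_edge(member, RelationKind.IS_A, union.id)
    return out


def in_taxon(tree: TaxonomyTree, taxon_id: str, target_id: str) -> bool:
    """True iff ``target_id`` is an ancestor-or-self of ``taxon_id``.

    Reflexive — a gene product from exactly the constrained taxon passes.
    For a union target the tree must be materialised; membership then
    holds iff the taxon sits under some member.  Unknown ids raise rather
    than silently answering False.
    """
    tree.graph.require(taxon_id)
    tree.graph.require(target_id)
    return target_id in tree.ancestors_or_self(taxon_id)


def lca(tree: TaxonomyTree, a: str, b: str) -> str:
    """Least common ancestor of two (non-union) taxa in the tree."""
    for t in (a, b):
        if TaxonomyTree.is_union(t):
            raise ValueError(f"lca is defined on plain taxa, got union {t}")
    chain_a = tree.chain_to_root(a)
    ancestors_b = set(tree.chain_to_root(b))
    for node in chain_a:  # deepest-first
        if node in ancestors_b:
            return node
    raise ValueError(f"taxa {a} and {b} share no ancestor (disconnected tree)")


def build_slim(tree: TaxonomyTree, species: set[str]) -> TaxonomyTree:
    """Reduce the taxonomy to ``species`` plus all pairwise LCAs.

    The slim node set is exactly ``species`` united with the least common
    ancestor of every species pair; each slim node is rewired with one
    is_a edge to its nearest strict ancestor that is itself in the slim
    (slim roots get none).  Internal nodes are accepted as seeds — useful
    when annotations exist at genus level.
    """
    if not species:
        raise ValueError("empty species set: a slim needs at least one seed")
    for s in sorted(species):
        tree.graph.require(s)

    slim_nodes = set(species)
    for a, b in combinations(sorted(species), 2):
        slim_nodes.add(lca(tree, a, b))

    slim_graph = OntologyGraph()
    for node in sorted(slim_nodes):
        slim_graph.add_term(tree.graph.require(node))
    for node in sorted(slim_nodes):
        for ancestor in tree.chain_to_root(node)[1:]:
            if ancestor in slim_nodes:
                slim_graph.add_edge(node, RelationKind.IS_A, ancestor)
                break

    return TaxonomyTree(
        graph=slim_graph,
        rank={t: r for t, r in tree.rank.items() if t in slim_nodes},
        synonyms={t: list(s) for t, s in tree.synonyms.items() if t in slim_nodes},
    )


def read_ncbi_dump(nodes_stream, names_stream) -> TaxonomyTree:
    """Import an NCBI taxonomy dump (nodes.dmp / names.dmp) as a tree.

    Thin convenience importer for the pipe-delimited dump format;
    preserves scientific names, synonyms and taxonomic rank.  All tests
    and fixtures use the OBO dialect, so this is never required.
    """
    parent_of: dict[str, str] = {}
    rank: dict[str, str] = {}
    for line in nodes_stream:
        fields = [f.strip() for f in line.rstrip("\n").split("|")]
        if len(fields) < 3 or not fields[0]:
            continue
        tax_id, parent_id = fields[0], fields[1]
        parent_of[tax_id] = parent_id
        if fields[2]:
            rank[f"NCBITaxon:{tax_id}"] = fields[2]

    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for line in names_stream:
        fields = [f.strip() for f in line.rstrip("\n").split("|")]
        if len(fields) < 4 or not fields[0]:
            continue
        tax_id, name, name_class = fields[0], fields[1], fields[3]
        curie = f"NCBITaxon:{tax_id}"
        if name_class == "scientific name":
            names[curie] = name
        elif name_class in ("synonym", "equivalent name", "common name"):
            synonyms.setdefault(curie, []).append(name)

    graph = OntologyGraph()
    for tax_id in sorted(parent_of, key=int):
        curie = f"NCBITaxon:{tax_id}"
        graph.add_term(
            Term(id=curie, name=names.get(curie, ""), namespace="taxonomy")
        )
    for tax_id, parent_id in sorted(parent_of.items(), key=lambda kv: int(kv[0])):
        if tax_id == parent_id:  # NCBI encodes the root as its own parent
            continue
        graph.add_edge(
            f"NCBITaxon:{tax_id}", RelationKind.IS_A, f"NCBITaxon:{parent_id}"
        )
    return TaxonomyTree(graph=graph, rank=rank, synonyms=synonyms)
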