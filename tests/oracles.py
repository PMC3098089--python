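"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates exhaustively and shares no traversal code with
the package: path-fold enumeration for the reasoner, ancestor-set
intersection for LCAs, and a double loop for constraint seeding.
"""

from gotaxon.ontology_model import PROPAGATING_RELATIONS


def entailed_by_path_enumeration(graph, start, entries):
    """Left-fold every simple propagating path from ``start``.

    Returns {(endpoint, folded relation)} for every path whose fold stays
    defined; a fold that hits an undefined pair entails nothing and the
    path is not extended (None composed with anything stays undefined).
    """
    results = set()

    def dfs(node, folded, visited):
        for edge in sorted(graph.out_edges(node)):
            if edge.relation not in PROPAGATING_RELATIONS:
                continue
            if edge.object in visited:
                continue
            new_fold = edge.relation if folded is None else entries.get(
                (folded, edge.relation)
            )
            if new_fold is None:
                continue
            results.add((edge.object, new_fold))
            dfs(edge.object, new_fold, visited | {edge.object})

    dfs(start, None, frozenset({start}))
    return results


def closure_by_path_enumeration(graph, start):
    """Endpoints of all simple propagating paths, plus the start itself."""
    reached = {start}

    def dfs(node, visited):
        for edge in graph.out_edges(node):
            if edge.relation not in PROPAGATING_RELATIONS:
                continue
            if edge.object in visited:
                continue
            reached.add(edge.object)
            dfs(edge.object, visited | {edge.object})

    dfs(start, frozenset({start}))
    return reached


def taxon_ancestor_chain(tree, taxon):
    """[taxon, parent, ...] by scanning raw is_a edges (no TaxonomyTree API)."""
    chain = [taxon]
    while True:
        parents = [
            e.object
            for e in tree.graph.edges
            if e.subject == chain[-1]
            and e.relation.value == "is_a"
            and not e.object.startswith("NCBITaxon_Union:")
        ]
        if not parents:
            return chain
        chain.append(parents[0])


def lca_by_ancestor_sets(tree, a, b):
    """Deepest common member of the two root chains."""
    chain_a = taxon_ancestor_chain(tree, a)
    chain_b = set(taxon_ancestor_chain(tree, b))
    common = [t for t in chain_a if t in chain_b]
    return common[0]


def slim_by_pairwise_lca(tree, species):
    """The slim node set built the obvious way: species plus all pair LCAs."""
    nodes = set(species)
    ordered = sorted(species)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            nodes.add(lca_by_ancestor_sets(tree, a, b))
    return nodes


def seeding_by_double_loop(go_graph, annotations, tree, focus, sisters,
                           min_sister):
    """Candidate classes by explicit (class, annotation) double loop."""
    candidates = []
    for go_class in sorted(go_graph.terms):
        if not go_class.startswith("GO:"):
            continue
        focus_n = 0
        sister_n = 0
        for ann in annotations:
            supported = closure_by_path_enumeration(go_graph, ann.go_class)
            if go_class not in supported:
                continue
            chain = taxon_ancestor_chain(tree, ann.taxon)
            if focus in chain:
                focus_n += 1
            elif any(s in chain for s in sisters):
                sister_n += 1
        if focus_n == 0 and sister_n >= min_sister:
            candidates.append((go_class, focus_n, sister_n))
    return candidates
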