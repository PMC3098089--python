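"""Brute-force reference computations used by the acceptance script.

Exhaustive enumeration only; shares no traversal code with the package.
"""

from gotaxon.ontology_model import PROPAGATING_RELATIONS


def entailed_by_paths(graph, start, entries):
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


def closure_by_paths(graph, start):
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


def _chain(tree, taxon):
    chain = [taxon]
    while True:
        parents = [
            e.object
            for e in tree.graph.edges
            if e.subject == chain[-1] and e.relation.value == "is_a"
        ]
        if not parents:
            return chain
        chain.append(parents[0])


def slim_by_pairwise(tree, species):
    nodes = set(species)
    ordered = sorted(species)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            chain_b = set(_chain(tree, b))
            nodes.add(next(t for t in _chain(tree, a) if t in chain_b))
    return nodes
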