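import random

import pytest

from gotaxon.checker import Annotation, ConstraintKind, TaxonConstraint
from gotaxon.fixtures import random_instance
from gotaxon.ontology_model import OntologyGraph, RelationKind, Term
from gotaxon.seeding import suggest_constraints, write_candidates, VETTING_NOTE
from gotaxon.taxonomy import TaxonomyTree
from oracles import seeding_by_double_loop


@pytest.fixture()
def plant_world():
    """A tiny GO + taxonomy where 'stipule development' is plant-only data.

    stipule development has annotations only from Arabidopsis; the metazoan
    sister clade has annotations to other classes, so a never_in(Metazoa)
    candidate should appear — illustrating that the heuristic mirrors
    under-annotation, which is why candidates require manual vetting.
    """
    go = OntologyGraph()
    for term_id, name in [
        ("GO:0000001", "biological_process"),
        ("GO:0010100", "stipule development"),
        ("GO:0020200", "locomotion"),
    ]:
        go.add_term(Term(id=term_id, name=name, namespace="biological_process"))
    go.add_edge("GO:0010100", RelationKind.IS_A, "GO:0000001")
    go.add_edge("GO:0020200", RelationKind.IS_A, "GO:0000001")

    tax = OntologyGraph()
    for taxon in ["NCBITaxon:1", "NCBITaxon:2759", "NCBITaxon:33090",
                  "NCBITaxon:33208", "NCBITaxon:3702", "NCBITaxon:7227"]:
        tax.add_term(Term(id=taxon, namespace="taxonomy"))
    for child, parent in [
        ("NCBITaxon:2759", "NCBITaxon:1"),
        ("NCBITaxon:33090", "NCBITaxon:2759"),  # Viridiplantae
        ("NCBITaxon:33208", "NCBITaxon:2759"),  # Metazoa (sister)
        ("NCBITaxon:3702", "NCBITaxon:33090"),
        ("NCBITaxon:7227", "NCBITaxon:33208"),
    ]:
        tax.add_edge(child, RelationKind.IS_A, parent)
    tree = TaxonomyTree(graph=tax)

    annotations = [
        Annotation("TAIR:A1", "GO:0010100", "IDA", "P", "NCBITaxon:3702"),
        Annotation("TAIR:A2", "GO:0010100", "IMP", "P", "NCBITaxon:3702"),
        Annotation("FB:F1", "GO:0020200", "IDA", "P", "NCBITaxon:7227"),
    ]
    return go, tree, annotations


class TestSuggestConstraints:
    def test_underannotated_class_yields_vetting_flagged_candidate(self, plant_world):
        go, tree, annotations = plant_world
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33208", min_sister_annotations=2
        )
        by_class = {c.go_class: c for c in candidates}
        stipule = by_class["GO:0010100"]
        assert stipule.kind is ConstraintKind.NEVER_IN
        assert stipule.focus_count == 0 and stipule.sister_count == 2
        assert stipule.note == VETTING_NOTE

    def test_class_annotated_in_both_clades_is_not_a_candidate(self, plant_world):
        go, tree, annotations = plant_world
        annotations = annotations + [
            Annotation("FB:F2", "GO:0010100", "IEA", "P", "NCBITaxon:7227")
        ]
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33208", min_sister_annotations=1
        )
        assert "GO:0010100" not in {c.go_class for c in candidates}

    def test_closure_propagated_support_reaches_ancestors(self, plant_world):
        go, tree, annotations = plant_world
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33090", min_sister_annotations=1
        )
        # locomotion is annotated only in the metazoan sister; the root
        # class gets closure support from both sides so is not a candidate
        assert {c.go_class for c in candidates} == {"GO:0020200"}

    def test_root_focus_taxon_errors(self, plant_world):
        go, tree, annotations = plant_world
        with pytest.raises(ValueError, match="root"):
            suggest_constraints(go, annotations, tree, "NCBITaxon:1", 1)

    def test_threshold_is_anti_monotone(self, plant_world):
        go, tree, annotations = plant_world
        previous = None
        for threshold in (1, 2, 3, 4):
            got = {
                c.go_class
                for c in suggest_constraints(
                    go, annotations, tree, "NCBITaxon:33208", threshold
                )
            }
            if previous is not None:
                assert got <= previous
            previous = got

    def test_existing_equal_or_stricter_constraint_suppresses(self, plant_world):
        go, tree, annotations = plant_world
        existing = [
            TaxonConstraint("GO:0010100", ConstraintKind.NEVER_IN, "NCBITaxon:33208")
        ]
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33208", 1,
            existing_constraints=existing,
        )
        assert "GO:0010100" not in {c.go_class for c in candidates}
        # an only_in on a disjoint clade is equally exclusionary
        existing = [
            TaxonConstraint("GO:0010100", ConstraintKind.ONLY_IN, "NCBITaxon:33090")
        ]
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33208", 1,
            existing_constraints=existing,
        )
        assert "GO:0010100" not in {c.go_class for c in candidates}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle_on_random_corpora(self, seed):
        inst = random_instance(seed, n_go_terms=15, n_taxa=12,
                               n_constraints=0, n_annotations=0)
        rng = random.Random(seed)
        taxa = sorted(inst.tree.graph.terms)
        species = sorted(inst.tree.leaves())
        go_ids = sorted(inst.go_graph.terms)
        annotations = [
            Annotation(f"DB:{i}", rng.choice(go_ids), "IEA", "P",
                       rng.choice(species))
            for i in range(30)
        ]
        # pick a non-root focus with at least one sister
        focus = None
        for candidate in taxa:
            parent = inst.tree.parent(candidate)
            if parent is None:
                continue
            siblings = [
                e.subject for e in inst.tree.graph.iter_edges()
                if e.object == parent and e.relation is RelationKind.IS_A
                and e.subject != candidate
            ]
            if siblings:
                focus, sisters = candidate, sorted(siblings)
                break
        if focus is None:
            pytest.skip("degenerate random tree without sisters")
        got = suggest_constraints(
            inst.go_graph, annotations, inst.tree, focus, 2
        )
        expected = seeding_by_double_loop(
            inst.go_graph, annotations, inst.tree, focus, sisters, 2
        )
        assert [(c.go_class, c.focus_count, c.sister_count) for c in got] == expected


class TestCandidateReport:
    def test_tsv_has_blank_verdict_column(self, plant_world):
        go, tree, annotations = plant_world
        candidates = suggest_constraints(
            go, annotations, tree, "NCBITaxon:33208", 1
        )
        text = write_candidates(candidates)
        header, *rows = text.splitlines()
        assert header.split("\t")[-1] == "verdict"
        assert all(r.endswith("\t") for r in rows)
        assert any(VETTING_NOTE in r for r in rows)
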