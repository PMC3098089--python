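import pytest

from gotaxon.checker import (
    Annotation,
    ConstraintIndex,
    ConstraintKind,
    TaxonConstraint,
    ViolationReport,
    check_annotation,
    check_annotation_set,
    effective_constraints,
    summarize,
)
from gotaxon.fixtures import random_instance
from gotaxon.ontology_model import TermNotFoundError


def annotation(go_class, taxon, **kw):
    defaults = dict(gene_product="DB:X", evidence_code="IEA", aspect="P")
    defaults.update(kw)
    return Annotation(go_class=go_class, taxon=taxon, **defaults)


class TestEffectiveConstraints:
    def test_lactation_inherits_the_mammalia_restriction(self, fx):
        found = effective_constraints(fx.go_graph, fx.constraints, "GO:0007595")
        assert [(c.go_class, c.kind, c.taxon) for c, _ in found] == [
            ("GO:0030879", ConstraintKind.ONLY_IN, "NCBITaxon:40674")
        ]
        assert found[0][1] == ("GO:0007595", "GO:0030879")

    def test_pep_carboxykinase_c4_sees_both_narrow_and_union_constraints(self, fx):
        found = effective_constraints(fx.go_graph, fx.constraints, "GO:0009762")
        origins = {(c.go_class, c.taxon) for c, _ in found}
        assert origins == {
            ("GO:0009760", "NCBITaxon:33090"),
            ("GO:0015979", "NCBITaxon_Union:0000021"),
        }

    def test_unconstrained_class_has_none(self, fx):
        assert effective_constraints(fx.go_graph, fx.constraints, "GO:0006412") == []

    def test_unknown_class_errors(self, fx):
        with pytest.raises(TermNotFoundError):
            effective_constraints(fx.go_graph, fx.constraints, "GO:4242424")


class TestCheckAnnotation:
    @pytest.mark.parametrize(
        "go_class, taxon, expected_origins",
        [
            # chicken -> lactation: outside Mammalia
            ("GO:0007595", "NCBITaxon:9031", ["GO:0030879"]),
            # platypus -> lactation: mammal, passes
            ("GO:0007595", "NCBITaxon:9258", []),
            # baker's yeast -> secretory granule: never_in Ascomycota
            ("GO:0030141", "NCBITaxon:4932", ["GO:0030141"]),
            # a basidiomycete fungus passes the Ascomycota exclusion
            ("GO:0030141", "NCBITaxon:5270", []),
            # Drosophila -> photosynthesis, light reaction: union constraint
            # inherited through part_of
            ("GO:0019684", "NCBITaxon:7227", ["GO:0015979"]),
            # Euglena -> PEP carboxykinase C4: passes the union, fails the
            # narrower Viridiplantae restriction
            ("GO:0009762", "NCBITaxon:3039", ["GO:0009760"]),
            # regulates link does not propagate the lactation restriction
            ("GO:1903487", "NCBITaxon:9031", []),
            # E. coli -> nuclear translation: nucleus constraint via occurs_in
            ("GO:0099999", "NCBITaxon:562", ["GO:0005634"]),
            # fission yeast -> spindle pole body organization: a fungus, passes
            ("GO:0051300", "NCBITaxon:4896", []),
        ],
    )
    def test_worked_examples(self, fx, go_class, taxon, expected_origins):
        violations = check_annotation(
            annotation(go_class, taxon), fx.go_graph, fx.full_tree, fx.constraints
        )
        assert [v.origin_class for v in violations] == expected_origins

    def test_arabidopsis_violates_both_constraints_on_a_mammal_class(self, fx):
        # conjunction semantics: every violated constraint is reported
        extra = TaxonConstraint("GO:0007595", ConstraintKind.ONLY_IN,
                               "NCBITaxon:32525")  # Theria, narrower
        constraints = sorted(fx.constraints + [extra],
                             key=TaxonConstraint.sort_key)
        violations = check_annotation(
            annotation("GO:0007595", "NCBITaxon:3702"),
            fx.go_graph, fx.full_tree, constraints,
        )
        assert {v.origin_class for v in violations} == {"GO:0030879", "GO:0007595"}

    def test_unknown_taxon_is_an_error_not_a_pass_or_violation(self, fx):
        with pytest.raises(TermNotFoundError):
            check_annotation(
                annotation("GO:0007595", "NCBITaxon:424242"),
                fx.go_graph, fx.full_tree, fx.constraints,
            )

    def test_violation_paths_are_real_edge_paths(self, fx):
        violations = check_annotation(
            annotation("GO:0099999", "NCBITaxon:562"),
            fx.go_graph, fx.full_tree, fx.constraints,
        )
        (v,) = violations
        assert v.path[0] == "GO:0099999" and v.path[-1] == v.origin_class
        edge_pairs = {(e.subject, e.object) for e in fx.go_graph.edges}
        for a, b in zip(v.path, v.path[1:]):
            assert (a, b) in edge_pairs

    def test_refinement_only_adds_violations(self, fx):
        # annotating to a descendant can only add violations relative to
        # its ancestor (closure monotonicity)
        for taxon in ("NCBITaxon:9031", "NCBITaxon:3039", "NCBITaxon:3702"):
            parent_violations = check_annotation(
                annotation("GO:0009760", taxon),
                fx.go_graph, fx.full_tree, fx.constraints,
            )
            child_violations = check_annotation(
                annotation("GO:0009762", taxon),
                fx.go_graph, fx.full_tree, fx.constraints,
            )
            parent_keys = {(v.constraint, v.origin_class) for v in parent_violations}
            child_keys = {(v.constraint, v.origin_class) for v in child_violations}
            assert parent_keys <= child_keys


class TestCheckAnnotationSet:
    def test_fixture_gaf_yields_exactly_the_expected_violations(self, fx):
        report = check_annotation_set(
            fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints
        )
        got = [
            (v.annotation.gene_product, v.annotation.go_class,
             v.origin_class, v.constraint.kind.value, v.constraint.taxon)
            for v in report.violations
        ]
        assert sorted(got) == sorted(fx.expected_violations)
        assert report.problems == []

    def test_empty_gaf(self, fx):
        report = check_annotation_set([], fx.go_graph, fx.full_tree, fx.constraints)
        assert report.violations == [] and report.totals == {}

    def test_duplicated_rows_are_not_deduplicated(self, fx):
        chicken = [r for r in fx.gaf_rows if r.db_object_id == "P00001"]
        report = check_annotation_set(
            chicken * 2, fx.go_graph, fx.full_tree, fx.constraints
        )
        assert len(report.violations) == 2

    def test_totals_count_every_resolvable_row_once_per_grouping(self, fx):
        report = check_annotation_set(
            fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints
        )
        for group in ("evidence_code", "aspect"):
            total = sum(n for (g, _), n in report.totals.items() if g == group)
            assert total == len(fx.gaf_rows)

    def test_unknown_ids_become_problem_rows(self, fx):
        import dataclasses
        rows = [
            dataclasses.replace(fx.gaf_rows[0], go_id="GO:4242424"),
            dataclasses.replace(fx.gaf_rows[1], taxon_field=("taxon:424242",)),
        ]
        report = check_annotation_set(rows, fx.go_graph, fx.full_tree, fx.constraints)
        assert len(report.problems) == 2
        assert report.violations == [] and report.totals == {}
        reasons = sorted(reason for _, reason in report.problems)
        assert "unknown GO class" in reasons[0]
        assert "unknown taxon" in reasons[1]

    def test_ignore_list_suppresses_but_tallies(self, fx):
        report = check_annotation_set(
            fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints,
            ignore_gene_products={"UniProtKB:P00001"},
        )
        assert len(report.suppressed) == 1
        assert len(report.violations) == len(fx.expected_violations) - 1
        suppressed_counts = sum(report.counts.values())
        # suppressed violations do not enter the error tallies
        full = check_annotation_set(
            fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints
        )
        assert suppressed_counts < sum(full.counts.values())

    def test_secondary_taxon_is_carried_but_not_checked(self, fx):
        import dataclasses
        row = dataclasses.replace(
            fx.gaf_rows[0], taxon_field=("taxon:9031", "taxon:11757")
        )
        report = check_annotation_set([row], fx.go_graph, fx.full_tree, fx.constraints)
        (v,) = report.violations
        assert v.annotation.taxon == "NCBITaxon:9031"
        assert v.annotation.secondary_taxon == "NCBITaxon:11757"


class TestDualImplementationEquivalence:
    def _keys(self, violations):
        return {
            (v.annotation.gene_product, v.annotation.source_line,
             v.constraint, v.origin_class, v.path)
            for v in violations
        }

    def test_on_worked_example(self, fx):
        index = ConstraintIndex(fx.go_graph, fx.constraints)
        for row in fx.gaf_rows:
            ann = _annotation_from_row(row)
            down = index.check(ann, fx.full_tree)
            up = check_annotation(ann, fx.go_graph, fx.full_tree, fx.constraints)
            assert self._keys(down) == self._keys(up)

    @pytest.mark.parametrize("seed, rate", [(0, 0.0), (1, 0.3), (2, 1.0)])
    def test_on_random_instances(self, seed, rate):
        inst = random_instance(seed, n_annotations=25, violation_rate=rate)
        index = ConstraintIndex(inst.go_graph, inst.constraints)
        from gotaxon.checker import gaf_taxon_to_curie
        for row in inst.gaf_rows:
            ann = _annotation_from_row(row)
            up = check_annotation(ann, inst.go_graph, inst.tree, inst.constraints)
            down = index.check(ann, inst.tree)
            assert self._keys(up) == self._keys(down)


def _annotation_from_row(row):
    from gotaxon.checker import gaf_taxon_to_curie
    return Annotation(
        gene_product=f"{row.db}:{row.db_object_id}",
        go_class=row.go_id,
        evidence_code=row.evidence_code,
        aspect=row.aspect,
        taxon=gaf_taxon_to_curie(row.taxon_field[0]),
        source_line=row.line_number,
        symbol=row.db_object_symbol,
    )


class TestSummarize:
    def test_published_style_percentages_round_half_up(self):
        report = ViolationReport.from_tallies("evidence_code", {
            "EXP": (977, 5360),
            "TAS": (4070, 46888),
            "IEP": (0, 10129),
        })
        rows = {r.group_key: r.percent for r in summarize(report, "evidence_code")}
        assert rows == {"EXP": 18.23, "TAS": 8.68, "IEP": 0.00}

    def test_aspect_grouping_and_order(self):
        report = ViolationReport.from_tallies("aspect", {
            "C": (5602, 461910), "P": (237, 568306), "F": (35, 627858),
        })
        rows = summarize(report, "aspect")
        assert [r.group_key for r in rows] == ["P", "F", "C"]
        assert [r.percent for r in rows] == [0.04, 0.01, 1.21]

    def test_half_up_boundary(self):
        # 0.125% must round to 0.13, not bankers' 0.12
        report = ViolationReport.from_tallies("evidence_code", {"IEA": (1, 800)})
        (row,) = summarize(report, "evidence_code")
        assert row.percent == 0.13

    def test_evidence_rows_follow_canonical_order(self, fx):
        report = check_annotation_set(
            fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints
        )
        rows = summarize(report, "evidence_code")
        from gotaxon.checker import EVIDENCE_CODE_ORDER
        positions = [EVIDENCE_CODE_ORDER.index(r.group_key) for r in rows]
        assert positions == sorted(positions)
        assert all(0 <= r.percent <= 100 for r in rows)

    def test_errors_without_total_is_an_error(self):
        report = ViolationReport()
        report.counts[("evidence_code", "IEA")] = 3
        with pytest.raises(ValueError, match="no total"):
            summarize(report, "evidence_code")

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            summarize(ViolationReport(), "db")
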