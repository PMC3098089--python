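# gotaxon

Taxon-constraint checking for Gene Ontology annotations.

GO classes are written to be taxon neutral, but many carry implicit taxon
specificity: `lactation` only makes sense for mammals, `nucleus` only for
eukaryotes, `photosynthesis` only for the disjoint union of Viridiplantae,
Bacteria, Euglenozoa and Archaea. `gotaxon` makes that specificity explicit
as **taxon constraints** —

- `only_in_taxon(A, T)`: class A, its sub-types and its parts may annotate
  only gene products from taxon T or its sub-types;
- `never_in_taxon(A, T)`: class A, its sub-types and its parts may never
  annotate gene products from T or its sub-types —

propagates them through the ontology graph, and flags every annotation
whose species of origin is inconsistent with a constrained class. It is
aimed at annotation-pipeline maintainers and ontology curators who want a
pre-release sanity gate: a bacterial protein annotated to `lactation`
indicates a defect in either the annotation set or the ontology structure,
and this tool finds such defects mechanically.

## The inference rules

Constraint inheritance follows from relation composition over
`is_a` / `part_of` / `occurs_in` (the regulates relations are excluded:
regulating a process in another species is perfectly possible):

```
is_a(A,B),      is_a(B,C)      → is_a(A,C)
is_a(A,B),      part_of(B,C)   → part_of(A,C)
part_of(A,B),   is_a(B,C)      → part_of(A,C)
is_a(A,B),      occurs_in(B,C) → occurs_in(A,C)
occurs_in(A,B), is_a(B,C)      → occurs_in(A,C)
is_a(A,B), U = B ∨ C           → is_a(A,U)          (union materialization)

annotated(G,A), (is_a ∨ part_of ∨ occurs_in)(A,B) → annotated(G,B)
in_taxon(G,T),  is_a(T,T′)                        → in_taxon(G,T′)

only_in_taxon(A,T),  ¬in_taxon(G,T) → ¬annotated(G,A)   (violation)
never_in_taxon(A,T),  in_taxon(G,T) → ¬annotated(G,A)   (violation)
```

An annotation of gene product G to class A is therefore checked against
every constraint asserted anywhere in A's propagation closure, and all
violated constraints are reported (constraints are conjunctive: a class
narrowed to Viridiplantae is still checked against the broader union
constraint it refines). Negation is closed-world over the full NCBI-style
taxonomy — never a slim, so species added after a slim was cut are still
checked correctly.

The package also provides the supporting machinery: a least-common-ancestor
**taxonomy slim** generator for human-guided constraint editing, **union
taxon** materialization, a **constraint seeding** heuristic (classes
unannotated in a clade but annotated in its sisters; candidates always
require manual vetting), and deterministic violation/summary reports.

## Worked example

The bundled fixture encodes the motivating examples: a Mammalia-only
lactation branch, the photosynthesis branch with its union constraint and
Viridiplantae narrowing, an Ascomycota exclusion on secretory granule, a
Fungi-only spindle pole body organization, and a nucleus constraint
inherited by nuclear translation through `occurs_in`.

```
$ gotaxon fixture --out demo
$ gotaxon check --go demo/go.obo --taxonomy demo/taxonomy.obo \
    --triggers demo/taxon_go_triggers.obo --gaf demo/annotations.gaf \
    --out demo/taxon_violations.txt
rows read: 12 (parse errors: 0)
rows checked: 12
problem rows: 0
violations flagged: 5
violations suppressed: 0
$ echo $?
1
```

Exit 1 means violations were found (0 = clean, 2 = input error), so the
command can gate a release pipeline. Of the twelve GAF rows, exactly five
are flagged:

| gene product | annotated class | violated constraint |
|---|---|---|
| chicken protein | `lactation` | only_in Mammalia, inherited from `mammary gland development` |
| fly protein | `photosynthesis, light reaction` | only_in the four-clade union, inherited via `part_of` |
| *Euglena* protein | `PEP carboxykinase C4 photosynthesis` | only_in Viridiplantae (passes the union, fails the narrowing) |
| baker's-yeast protein | `secretory granule` | never_in Ascomycota |
| *E. coli* protein | `nuclear translation` | only_in Eukaryota on `nucleus`, inherited via `occurs_in` |

The platypus lactation row passes (a mammal), and the chicken row on
`regulation of lactation` passes because regulates edges never propagate
constraints. Each output row carries the constraint's origin class and the
full inheritance path (e.g. `GO:0099999>GO:0005634`), so every flag is
auditable.

The same checks are available as a library:

```python
from gotaxon import check_annotation_set, summarize
from gotaxon.fixtures import paper_fixture

fx = paper_fixture()
report = check_annotation_set(fx.gaf_rows, fx.go_graph, fx.full_tree, fx.constraints)
len(report.violations)            # 5
summarize(report, "evidence_code")  # per-evidence-code error rates
```

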