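# Methods

## The model

`gotaxon` treats annotation QC as rule-based inference over two graphs
sharing one data model (`OntologyGraph`: CURIE-identified terms plus typed
directed edges).

**The GO side** is a DAG over `is_a`, `part_of` and `occurs_in` (the
"true path rule" demands acyclicity, which `validate_graph` enforces as a
precondition of all reasoning). Regulates-family edges are stored but
excluded from every traversal: keeping them in the model lets the tests
assert, rather than assume, that regulation never transmits taxon
specificity — one can regulate a process carried out by another species.

**The taxonomy side** is a rooted `is_a` tree of NCBI-style taxa,
optionally extended with *union taxa*: named disjunctions (e.g. the
photosynthesis clades) used where no common superclass exists.
Materialization adds one `is_a` edge from each member into the union term,
after which a single reflexive-transitive closure algorithm
(`ancestors_or_self`) answers both plain and union membership. `in_taxon`
is reflexive by design: a gene product from exactly the constrained taxon
must pass.

**Checking.** An annotation of gene product G (species S) to class A
violates `only_in_taxon(B, T)` when B is in the propagation closure of A
and T is not an ancestor-or-self of S, and violates `never_in_taxon(B, T)`
when T is an ancestor-or-self of S. Negation is closed-world
(negation-as-failure over the taxonomy closure). Constraints along the
closure are conjunctive and all violated constraints are reported, one
violation per (annotation, constraint) pair; a duplicated GAF row is
deliberately flagged twice. Checking always consults the **full**
taxonomy, never a slim — a slim cut before a new species was annotated
would silently pass it.

Two readings of constraint inheritance are implemented and cross-checked
on every fixture and random instance: constraints pushed *down* from their
origin to every governed class (`ConstraintIndex`), and annotations walked
*up* through their closure (`check_annotation`). Their violation sets,
origins and witness paths must coincide; the acceptance suite asserts
this.

## Relation composition

`entailed_relations` answers the distinct question of *which named
relation* holds between two classes, by folding a composition table along
edge paths. The base table holds five compositions (identity-like folds
with `is_a` on either side of `part_of`/`occurs_in`, plus
`is_a`∘`is_a`). Three extensions are flags on `CompositionTable`:

| flag | adds | default | why |
|---|---|---|---|
| `part_of_transitive` | `part_of`∘`part_of` → `part_of` | on | part_of is transitive by its formal definition |
| `occurs_in_over_part_of` | `occurs_in`∘`part_of` → `occurs_in` | off | experimental |
| `occurs_in_transitive` | `occurs_in`∘`occurs_in` → `occurs_in` | off | experimental |

Violation checking never depends on these flags: annotation propagation is
plain reachability (the `annotated` rule recurses over single edges), so
the flags affect only the named-relation report (`gotaxon entail`).

Path semantics are *left-fold*: a path entails the relation obtained by
composing its edge labels left to right, and a fold that hits an undefined
pair entails nothing. The implementation propagates (node, folded
relation) states through a worklist rather than enumerating paths; this is
exact for any flag combination, including the experimental ones, for
which the table is **not** associative ((`occurs_in`∘`part_of`)∘`occurs_in`
is defined while `occurs_in`∘(`part_of`∘`occurs_in`) is not). The default
and minimal tables are associative on all 27 relation triples (asserted by
test), so fold order is immaterial for shipping configurations.

## Taxonomy slims

`build_slim` implements module extraction for human-guided constraint
editing: the slim node set is the annotated species plus the least common
ancestor of every species pair; each slim node is rewired with one `is_a`
edge to its nearest strict ancestor within the slim. Nearest-ancestor
rewiring is the minimal reading of "includes only those taxa" — full
parent chains would drag in every intermediate rank. Internal taxa are
accepted as seeds (annotations at genus level are real). The node count is
bounded by 2·|species| − 1 (each pairwise LCA is a branching node of the
induced subtree). Slims are an editing convenience only; the checker API
takes the full tree by contract.

## File formats

The OBO dialect is the minimal subset the constraint files need: `[Term]`
stanzas, `is_a:`, `relationship:` (part_of, occurs_in, the regulates
family, only_in_taxon, never_in_taxon), `union_of:`. Constraint
relationship lines surface as `TaxonConstraint` records anchored at their
subject, not as graph edges; union stanzas surface as `UnionTaxon`.
Unknown tags are preserved verbatim per stanza and re-emitted on write, so
round-trips are lossless for tags the tool does not interpret (the
taxonomy reader lifts `synonym:` and `property_value: has_rank` back out
of these). Writes are sorted by term id, making every output
byte-reproducible. The regulates sub-relations are normalised to
`regulates` on write; in-memory round-trip identity is the contract, not
file-level identity.

GAF 2.0 (17 columns) is the supported annotation dialect; 15-column GAF
1.0 rows are padded in permissive mode. The taxon column may carry two
tokens; the first (the gene product's own species) is checked and an
interaction-partner token is carried into the report unchecked. Rows with
unknown classes, obsolete classes or unknown taxa are collected as problem
rows — a distinct outcome from both pass and violation — and never enter
the tallies.

The violations file schema (origin class + inheritance path per row) is
this package's own choice: flagged sets go back to the groups that
produced the annotations, which demands every flag be auditable without
re-running the tool. Percentages in summaries are errors/total × 100,
rounded half-up to two decimals (`decimal`, not float rounding), grouped
by evidence code (canonical 17-code order) or by GO aspect (P, F, C).
One published cellular-component tally (5602 errors of 461910) computes
to 1.21% where 1.12% was printed; the computed value is taken as correct
and the printed one treated as a typographical slip.

## Constraint seeding

`suggest_constraints` proposes `never_in(focus)` candidates: classes with
zero closure-propagated annotations from species under the focus clade
and at least a caller-chosen number from its sister clades. The threshold
has no default — it is a curation policy, not a property of the data.
Candidates are proposals only (absence of annotation usually means absence
of curation, not absence of biology), are labelled "requires manual
vetting", carry both supporting counts, and are suppressed when an
existing constraint is already equally or more exclusionary. Promotion to
`only_in` is left to humans.

## Synthetic data

`paper_fixture` hand-builds a 21-class GO fragment, a 24-taxon tree and
one union term around the motivating examples (lactation/Mammalia,
photosynthesis union + C4 narrowing, secretory granule/Ascomycota,
spindle pole body/Fungi, nucleus inherited by nuclear translation via
`occurs_in`, and a regulates-linked regulation class as a negative
control), with a 12-row GAF containing five known-bad rows. Real GO and
NCBI identifiers are used where standard; the `nuclear translation` id
(GO:0099999) and the tree topology beyond the named clades are fixture
inventions. The expected violation list is a hand-checked oracle, also
verified against the brute-force checker.

`random_instance(seed, ...)` generates seeded random problems: a GO DAG
(each non-root term gets 1–3 parents, relation drawn is_a 0.7 / part_of
0.2 / occurs_in 0.1), a random rooted taxonomy whose leaves form the
species pool, constraints on internal GO terms with internal taxa, and
annotations drawn uniformly from the enumerated violating (class,
species) pairs with probability `violation_rate` and from the clean pairs
otherwise. Ground truth is labelled by `brute_force_violations`, an
independent full-path-enumeration checker; the plant list is therefore
exact even when one row trips several constraints. Identical seeds give
byte-identical instances (SHA-256 asserted). Defaults (30 classes, 20
taxa, 5 constraints, 50 annotations) keep brute-force labelling cheap
while exercising multi-parent inheritance; production-scale graphs
(tens of thousands of classes) are out of scope for the generator, so
passing tests demonstrate correctness of the inference, not performance
at GO scale, and say nothing about the curatorial quality of any real
constraint set.

## Numerical and degenerate-input choices

- All orderings are lexicographic by CURIE; witness paths are breadth-first
  shortest with smallest-id tie-break, so reports are byte-stable.
- Duplicate edges and hierarchy self-loops are rejected at insertion;
  cycles are a validation failure, not handled in-reasoner.
- Obsolete terms stay in the term map but may carry no edges; annotations
  to them become problem rows.
- Empty species set → error in `build_slim`; single species → slim with no
  edges; `lca(x, x) = x`.
- Unknown taxon or class ids raise — membership queries never silently
  answer false.
- An ignore-listed gene product's violations are suppressed from the
  report file but tallied separately (horizontal-transfer cases that
  curators chose to leave flagged but unreported).

## Known limitations

- The OBO subset omits intersections, disjointness axioms and most of OBO
  1.4; unknown tags survive round-trips but are not interpreted.
- Union members are asserted disjoint-by-construction but this is not
  verified against deeper taxonomy structure beyond the
  no-member-is-an-ancestor-of-another check.
- The seeding heuristic inherits every bias of annotation coverage; its
  output is a work queue for curators, never a constraint source.
- The NCBI dump importer reads `nodes.dmp`/`names.dmp` only; merged or
  deleted taxa files are not consulted.
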