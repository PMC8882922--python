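# Methods

## Model

A dataset is five flat tables plus a compound dictionary (TSV, pinned
lowercase snake_case headers, `;`-separated multi-value cells; a
`column_map` argument on every reader aliases other dialects):

* `network.tsv` — signed TF→gene interactions with optional promoter id;
* `conformations.tsv` — one row per TF conformation: `apo`/`holo`,
  `active`/`inactive` (DNA-binding-competent or not), bound effectors
  (holo rows must list ≥1, apo rows none);
* `products.tsv` — gene products; >1 encoding gene means a hetero-complex;
* `reactions.tsv` — reactants, products, catalyst (a product id or a TF
  id), type (`enzymatic`, `transport`, `tf_effector_binding`, `other`),
  reversibility;
* `ontology.tsv` — compound is-a edges, child → parent, required acyclic;
* `compounds.tsv` — canonical names and synonyms.

Effector and reaction-participant tokens are resolved against the
compound dictionary (id, name or synonym, case-insensitive) at load
time; all matching downstream operates on canonical compound ids only.
Compartments are collapsed: transport is a reaction with the moved
compound on both sides, and the feedback scan treats it like any other
reaction.

### Unit assembly

The elementary unit of TF *t* contains: the genes *G(t)* targeted by *t*
(any effect sign, including `dual`); every product with at least one
encoding gene in *G(t)* (the inclusive rule for hetero-complexes;
`require_all_complex_genes=True` demands all component genes); every
reaction whose catalyst is one of those products, excluding
`tf_effector_binding` rows and reactions catalysed by *t* itself (the
latter feed the enzymatic-TF tier); and the union of effectors over
*t*'s holo conformations. Complex units partition genes by their exact
regulating-TF set — exactness makes the partition property (disjoint
blocks covering all regulated genes) testable — and keep blocks with ≥2
anchors by default.

### Feedback tiers

Priority is fixed: `DIRECT` > `ENZYMATIC_TF` > `CLASS_SUGGESTED` >
`CASCADE`, with `NO_EFFECTOR` short-circuiting and `NOT_FOUND`
otherwise. The enzymatic-TF tier outranks the class tier because a TF's
own catalysis of its effector is exact evidence while a class match is
only a curation suggestion. Matching is direction-blind and any-match
over multiple effectors. Each tier is individually toggleable; the
headline "direct feedback fraction" reported by `summarize` uses the
direct tier only, over results with a known effector, rounded
half-away-from-zero.

Class matching takes the full transitive closure of the is-a DAG in both
directions by default (`class_max_hops` limits the path length); exact
matches (distance 0) are never reported at this tier. The cascade tier
runs a breadth-first search over the TF→TF graph — TF *x* regulates TF
*y* iff *x* targets a gene encoding *y*, where "encoding" is a
`regulator`-kind product row mapping *y* to its gene(s), with
gene-id = tf-id accepted as a fallback for minimal networks. Default
depth is 1 hop and direction `both`: downstream hops are needed for
RhaR→RhaS- and Cbl→CysB-style mediation, upstream hops for
AllR→AllS-style mediation. Each mediator is visited once, at its
shortest hop distance, so the evidence set at depth *d* is a subset of
that at depth *d* + 1.

### Response-logic rule

`predict_response(mode, active_state, effector_present)`: the TF is in
its DNA-binding-active form exactly when `active_state == "holo"` equals
the effector's presence; transcription increases iff the TF is active
and an activator, or inactive and a repressor. The rule is total on its
8-point domain, symmetric under flipping mode and active state together,
and antisymmetric under toggling effector presence. Dual-mode TFs are
out of this function's domain unless expanded into one activator and one
repressor record.

## Synthetic data

The generator is a pure function of (config, seed) over one
`random.Random` stream; table rows are emitted in construction order, so
equal inputs give byte-identical files. Per TF it plants one of six
categories — `DIRECT`, `CLASS`, `CASCADE_DOWN`, `CASCADE_UP`,
`ENZYMATIC_TF`, `NONE` — and always adds decoy genes, decoy reactions
over compounds unique to that TF, and the effector–TF binding reaction,
so negatives are non-vacuous and the binding exclusion is exercised.
Mediator TFs for cascade cases and global co-regulators are extra,
effector-less TFs outside the ground-truth table.

Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| category mix | 71 : 7 : 2 : 1 : 2 : 4, scaled by largest remainder | composition of the curated *E. coli* compendium (87 effector-bearing units) |
| effectors per TF | P(1,2,3,4) = 0.88, 0.09, 0.02, 0.01 (mean 1.16) | single-effector dominance with a small right tail, as in the compendium |
| genes per TF | uniform 2–5 | small-regulon scale; keeps brute-force checks instant |
| promoter co-regulation | 0.5 | ≈50 % of promoters are bound by >1 TF |
| class hop distance | 1 | stereoisomer-style subclass one is-a edge from the effector |

What the generator does **not** emulate: realistic stoichiometry or
pathway structure (decoy reactions are one-in/one-out), shared
metabolites between regulons (effectors and decoys are unique per TF, so
cross-unit coincidental matches never occur), operon structure, or
noise/errors in curation. Passing the planted-recovery test therefore
shows the algorithm is exact under clean, well-separated annotations; it
does not bound the suggestion rate of the class tier on real data, where
compound hierarchies are shared and dense.

## Numerical and design choices

* Percentages use round-half-away-from-zero (71/87 → 81.6 % → 82 %);
  an empty result set reports `None` rather than 0.
* Ties and orderings are broken lexicographically everywhere (unit maps,
  evidence rows, BFS neighbour order), making every scan deterministic.
* Duplicate network rows collapse with a logged warning; duplicate ids
  in any other table are errors.
* Degenerate inputs: an empty network yields an empty unit map; a TF
  with no holo row is `NO_EFFECTOR`; `cascade_depth < 1` is rejected.
* The cross-table validator requires every compound, catalyst and
  ontology endpoint to resolve, and at least one active conformation per
  TF with conformation rows.

## Verification

The test suite checks each operation against hand-enumerated examples
and against an independent brute-force oracle (naive filtering for unit
membership, fixpoint transitive closure, explicit path enumeration for
cascades) on hundreds of small random datasets, plus property tests for
the invariants: tier and cascade-depth monotonicity, binding-reaction
and reversibility no-ops, histogram mass conservation, partition
coverage, and serialisation round-trips. `scripts/acceptance.py`
recomputes the headline quantities from scratch at the problem sizes
stated there (20 TFs × 20 seeds for recovery; 87 TFs for the direct-tier
fraction; 500 TFs for distribution statistics).

## Limitations

* Feedback sign, strength and dynamics are out of scope; the scan
  establishes topology only.
* Non-allosteric sensing (two-component phosphorelay, covalent
  modification, protein–protein control) is representable only as
  product kinds, not mechanistically.
* The class tier deliberately over-suggests: every is-a relative within
  reach is reported, because deciding biological equivalence of a
  stereoisomer is a curation task, not an algorithmic one.
* Real regulatory databases ship in multiple flat-file dialects; only
  the pinned dialect plus per-column aliasing is supported, not a
  general schema mapper.
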