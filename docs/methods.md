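# Methods

## Scope and model

`eqsim` compares sources of entity–quality (EQ) phenotype annotations of
phylogenetic character states.  An annotation source maps character
states — keyed by (study, character, state) — to lists of EQ
annotations; each annotation is an Entity expression, a Quality
expression, and optionally a Related Entity expression over one or more
OBO ontologies.  Components may be named classes or post-compositions
(intersections and existential restrictions, e.g.
`('gland' and (part_of some 'pelvis'))`).

## Structural subsumption

Subsumption is computed structurally over an acyclic `is_a` graph with
four rules: reflexive–transitive closure for named classes (R1);
`(p some F) ⊑ (p some F′)` for every superclass `F′` of `F` (R2); an
intersection is subsumed by itself and by every superclass of each
conjunct (R3); and for a transitive property,
`(p some (p some F)) ⊑ (p some F′)`, applied to fixpoint (R4).  This is
the EL-style fragment that EQ post-compositions need.  It deliberately
omits named-class equivalence axioms, property hierarchies, and
`intersection_of`/`equivalent_to` OBO lines (ignored with a warning):
quality hierarchies in practice lack logical definitions over anatomy
terms, so named-class equivalences contribute nothing to these subsumer
sets.  `part_of` defaults to transitive, matching its declaration in the
anatomy/spatial ontologies this tool targets; other properties are
non-transitive unless declared.

Obsolete classes are retained for identifier resolution and error
messages but excluded from subsumption.  Intersections are flattened,
deduplicated and sorted by rendered form, so conjunct order never
affects equality or subsumer membership.

## Subsumer sets

A complete EQ annotation is a node in an ad hoc phenotype ontology.  Its
subsumer set is the disjoint union of two families:

1. **combinations**: SE × SQ × SR, the cross-product of the reflexive
   component superclass sets (SR = {absent} without a related entity) —
   a memory-saving equivalent of materializing a full cross-product
   ontology, which is prohibitive;
2. **expression superclasses** of
   `Q and (inheres_in some E) [and (towards some RE)]` under R1–R4,
   i.e. SQ, `(inheres_in some e)` for e ∈ SE, `(towards some r)` for
   r ∈ SR, and the expression itself.

The families are kept distinguishable ("tagged"): a bare quality counted
inside a combination and the same quality as an expression superclass
are distinct elements, and combinations with and without a related
entity never compare equal.  Each node is its own subsumer, which makes
Jaccard similarity exactly 1 on identical annotations.

## Metrics

* **Jsim** — |S₁ ∩ S₂| / |S₁ ∪ S₂| over the tagged subsumer sets.
* **Information content** — for a node N, `p(N)` is the annotation
  frequency of everything N subsumes divided by the corpus total;
  `I = −log p` (natural log; the normalized score is base-invariant),
  `In = I / Imax` with `Imax = −log(1/total)`.  The corpus counts every
  complete annotation of the selected sources (by default everything
  being compared); incomplete annotations have no resolvable node and
  are not counted.  A node subsuming nothing annotated gets `In = 1`
  (bounded, rather than infinite), with a logged note.
* **LCS similarity (IN)** — common subsumers are the intersection of two
  tagged subsumer sets; candidates are those not strictly subsuming
  another common subsumer; among candidates the highest-I node wins,
  ties broken lexicographically on rendering for deterministic reports.
  No common subsumer scores 0.  For frequency counting, an
  identity-shaped expression (`Q and inheres_in some E ...`) denotes the
  same class as its E–Q–RE combination and is decomposed accordingly;
  without this, the LCS of an annotation with itself would not equal the
  annotation's own IC whenever the corpus contains its descendants.
* **PP / PR** — means over test (resp. reference) annotations of their
  best Jsim match on the other side; exact transposes of each other.

Aggregation: per state, JSIM/IN take the maximum over all EQ pairs
("best match"); PP/PR are state-level by construction.  Per source pair,
the mean over shared states; states present on one side only are
excluded from the mean and reported.  A state with an incomplete EQ on
either side, or with no EQs, scores 0 on every metric
(`zeroed_for_incompleteness`); the empty-state behavior can be switched
to "skip".

Note that identical sources do **not** score 1 on IN: the LCS of an
annotation with itself is the annotation, and its `In` is below 1
whenever the corpus counts it more than once.  This is a property of the
frequency-based definition, not an implementation artifact; JSIM, PP and
PR are 1 in that situation.

## Rank statistics

Anderson's A = ((t−1)/t) Σᵢⱼ (O(i,j) − n/t)² / (n/t) over the t×t
source-by-rank count matrix, referred to χ² with (t−1)² df; Friedman's
F = 12/(n t (t+1)) Σᵢ (Rᵢ − n(t+1)/2)² with rank sums Rᵢ, χ² with t−1
df.  Survey rows must be full permutations; ragged surveys are pooled
over complete rows, and tied ranks are accepted only via an explicit
mid-rank option (with a warning), since the count-matrix formulas assume
integer ranks.

The paired Wilcoxon signed-rank test uses the Pratt convention (zero
differences enter the ranking of |d| but not the rank sums) with an
exact null distribution — a dynamic program over attainable signed-rank
sums, supporting mid-rank ties — for up to 25 nonzero differences, and a
normal approximation with continuity and tie/zero variance corrections
above.  The convention matters: p-values near a family-wise threshold
can flip under alternative zero-handling rules.  `bonferroni_threshold`
provides the α/m family-wise cutoff used when many condition pairs are
tested.

## Synthetic data generator

`gen_ontology` builds a seeded rooted DAG with an anatomy branch and an
attribute branch under the root (1–`max_parents` parents per class,
~10% of classes carrying a transitive `part_of` edge).  `gen_source_pair`
gives each state 1–3 complete reference EQs (entities and qualities from
the two branches, 20% with a related entity) and derives the test
source by one divergence mode per state:

* `exact` — identical annotations;
* `subsumption` — one component replaced by a *direct* is_a parent or
  child: one-level substitution keeps broader/narrower-term divergence
  more similar than sibling divergence, as the mode ordering intends,
  and is the realistic way curators disagree by generality;
* `sibling` — one component replaced by a term sharing a parent (falling
  back to the other component, then to a one-level substitution, then to
  an arbitrary in-pool term, so a divergent mode never returns an
  unchanged annotation);
* `unrelated` — every component replaced by a term with minimal ancestor
  overlap: on a merged multi-component ontology this yields annotations
  with no shared subsumers at all (Jsim exactly 0);
* `recompose` — the entity re-expressed as
  `(parent and (part_of some ancestor))`, emulating equivalent
  post-composition of the same anatomy;
* `missing` — one annotation dropped;
* `incomplete` — one annotation's entity left unresolvable, triggering
  the zero rule end to end.

Default mode probabilities (0.26 exact, 0.30 subsumption, 0.16 sibling,
0.08 unrelated, 0.10 recompose, 0.05 missing, 0.05 incomplete) are
illustrative of a plausible curation team, not estimates of any
particular one; all are configurable.  One master seed spawns
independent per-state streams, so adding states never perturbs earlier
ones.

What the generator does *not* emulate: natural-language character text
(there is no NLP step), real ontology topology (Uberon's depth and
multiple inheritance are only coarsely approximated by the random DAG),
and correlated curator behavior (modes are drawn independently per
state).  Passing tests on synthetic pairs therefore demonstrate the
correctness and calibration of the metrics, not the field consistency
levels of real curation teams.

## Numerical and design choices

* Natural logarithms throughout; `In` is base-invariant.
* Subsumer sets and superclass sets are memoized per graph; IC values
  per corpus.  Determinism is unaffected; reports are byte-identical
  across runs (state keys sorted, fixed float formatting).
* Label resolution in the expression grammar: exact label first, then
  synonym; ambiguity is an error listing the candidates, and unresolved
  labels report near-matches.
* The annotation interchange format is a flat TSV (one row per EQ;
  repeated state keys accumulate); the reader preserves unresolvable
  rows as incomplete annotations rather than dropping them, because the
  scoring rule must see them.
* OBO reading is a narrow, line-number-aware reader for the
  [Term]/[Typedef] fragment (id, name, synonym, is_a, relationship,
  is_obsolete, is_transitive) with load-time cycle and dangling-edge
  validation; merging is a set union with first-wins label conflicts
  (logged).
* Problem sizes in the test-suite and acceptance script (ontologies of
  16–60 classes, 25–400 states, 5–20 seeds) were chosen as the smallest
  scales at which the binomial and rank-correlation checks are
  well-powered.

## Known limitations

* No OWL-DL reasoning: named-class equivalences, property chains beyond
  self-transitivity, disjointness and cardinality are out of scope; a
  curated ontology whose subsumptions depend on logical definitions
  would yield fewer subsumers here than a full reasoner.
* Sub-property reasoning (e.g. specializations of `part_of`) is omitted,
  a potential divergence when replicating analyses run with a full
  reasoner.
* Only OBO flat files are read (no OWL/RDF-XML), and annotation tables
  only as the TSV dialect; the NeXML corpus embedding used by some
  archives is not parsed.
* Incomplete annotations are excluded from the IC corpus, so heavily
  incomplete machine output slightly lowers the corpus total.
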