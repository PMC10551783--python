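# Methods

This note documents the models, conventions and numerical choices behind
`relgraph`, and what the synthetic-data experiments do and do not show.

## Data model

The atomic observation is a sentence-level relation prediction: a source
paper ID, sentence, head and tail entity (CUI, surface name, entity type),
a relation label from a 125-label vocabulary whose index 0 is
"not a relation", a confidence in (0, 1], an article topic, a publication
date and a paper-level attention score.  Probabilities are softmax
outputs, so each record's confidence is taken at face value; no
recalibration is attempted.

Relation labels come in inverse-direction pairs (*may_treat* /
*may_be_treated_by*) plus self-inverse symmetric labels.  The inverse-pair
map is an involution with exactly one canonical member per pair.
Canonicalization rewrites a non-canonical record to its canonical label
with head and tail swapped; it is idempotent and, by construction,
commutes with aggregation.

## Triple aggregation

Aggregation merges records with identical (head, relation, tail) after
null removal and canonicalization.  Per edge:

* `n_sources` counts **distinct source papers**, not sentences — the
  plausibility conditions downstream read "supported by at least two
  different texts", which is a per-paper notion;
* `prob_mean` and `prob_sum` run over **records** (a paper contributing
  two sentences contributes two probabilities).  This is the simplest
  reading of a per-edge probability mean/sum; a per-paper mean would need
  an extra within-paper reduction whose choice the data does not dictate.
* An edge is marked `inverse-collapsed` when at least one contributing
  record arrived in the non-canonical direction, so the original mix of
  directions remains visible after merging.

Conservation holds exactly: Σ `prob_sum` over edges equals Σ probability
over non-null records, and the merge is invariant to record order.

Credibility filters are deliberately strict readings:
the date window is inclusive on both ends (default 2022-06-01 to
2023-06-01); the attention filter keeps papers **strictly above** the mean
over all papers in the score table (papers missing from the table count as
0 and are logged, mirroring unindexed articles); the conclusive-language
rule matches case-insensitive word-boundary stems (the default list —
conclude, demonstrate, show, confirm, improve, reduce, effective,
efficacious — ships as editable YAML, since no canonical rule set exists).

## Knowledge graph and Adamic–Adar

The graph is a directed multigraph (parallel edges = different relation
labels between the same pair).  Self-loop triples are dropped with a
warning count rather than raised: they are almost always upstream
entity-normalization collisions, not signal.  Endpoints missing from the
entity table are synthesized with type `unknown` and logged.

Neighborhood statistics use the undirected projection with parallel edges
collapsed: "shared neighbors" is a direction-free notion, and multiple
relation labels between the same pair are one adjacency, not several.
Adamic–Adar uses the natural logarithm (the base only rescales all scores
monotonically, so rankings are unaffected).  A shared neighbor of two
distinct nodes necessarily has degree ≥ 2, so every term 1/ln|N(u)| is
finite.  Summation runs over the *sorted* shared-neighbor list, which
makes the floating-point result deterministic and exactly symmetric in
(x, y).

Exports use the Neo4j bulk-import CSV dialect with typed headers
(`node_id:ID,name,entity_type` and
`:START_ID,:END_ID,relation,direction,n_sources:int,prob_mean:float,prob_sum:float`),
RFC-4180 quoting and UTF-8; floats are written with `repr` so round trips
are bit-exact.  A node-link JSON export preserves all attributes.  No live
database driver is used: file-based import keeps the pipeline offline and
reproducible.

## Drug discovery

Relation labels are grouped into coarse classes (TREATS, AFFECTS,
ASSOCIATED, DRUG_DRUG_ASSOC, OTHER) by a user-editable YAML map.
Association classes are treated as symmetric — stored direction is ignored
when matching — while TREATS and AFFECTS respect direction, since therapy
and effect arrows are meaningful.

Existing drugs must satisfy all three conditions (gene-effect evidence,
disease-treatment evidence, per-edge `n_sources ≥ min_sources`, default
2).  `min_sources` applies to **every** evidence edge individually,
including the association edges to the target.

Novel-path enumeration grows candidates backwards from the target through
class-filtered neighborhoods and validates each required edge; the
independent test oracle instead enumerates all ordered typed node triples
exhaustively, so agreement is a meaningful cross-check.  Constraints per
the three 4-node patterns:

| pattern | nodes | template edges | qualifications |
|---|---|---|---|
| a | drug, disease₂, gene, target | drug→TREATS disease₂; disease₂–gene ASSOC; gene–target ASSOC | disease₂–target ASSOC |
| b | drug₁, disease₂, drug₂, target | drug₁→TREATS disease₂; drug₂→TREATS disease₂; drug₂→TREATS target | disease₂–target ASSOC; drug₁–drug₂ association |
| c | drug, gene₁, gene₂, target | drug→AFFECTS gene₁; gene₁–gene₂ ASSOC; gene₂–target ASSOC | gene₁–target ASSOC |

"Not directly connected" excludes a drug if **any** edge of any relation
class links it to the target in either direction.  Qualification edges
default to `min_sources = 1` (a separate knob from the template edges):
whether the two-text condition extends to qualifications is genuinely
open, so it is a flag rather than a hard-coded rule.  Paths are
deduplicated by node sequence and ranked by descending Adamic–Adar
(drug, target), ties broken by (pattern, drug ID).

## Topic analytics

Topic similarity is computed two ways because "correlation by amount and
diversity of relation" admits two natural readings, reported separately:
*amount* is the Pearson correlation of relation-proportion vectors over
the union label set (absent labels = 0; a zero-variance vector makes the
correlation undefined and the entry is reported as NaN, never coerced to
0); *diversity* is the Jaccard index of relation-presence sets.

PCA runs on proportion (not raw count) vectors to remove per-topic volume
effects, centered, with optional standardization.  The sign of each
principal axis is fixed by making its largest-magnitude loading positive
(lowest index wins ties), so embeddings are reproducible.  Equal-article
profiling subsamples each topic, seeded and without replacement, to the
minimum per-topic distinct-paper count; the retained paper set is kept on
the profile for provenance.

Entity-type strength counts, per unordered type pair, the number of
records and the number of distinct relation labels (inverse pairs
collapsed when a pair map is supplied); both matrices are symmetric by
construction and diversity never exceeds volume.

## Evaluation layer

Weighted precision/recall/F1 aggregate per-class metrics with weights
proportional to true-class support; undefined ratios (empty predicted or
true class) are reported as 0, the convention standard weighted-metric
implementations use.  Argmax label prediction breaks ties toward the
lowest label index.  The ensemble is Σ wᵢMᵢ / Σ wᵢ with nonnegative
weights summing to a positive value; whether weights are learned is out of
scope — they are caller input.  The precision-recall curve is
micro-averaged one-vs-rest over all labels except the null label: with 125
classes, per-class curves are noisy and macro averaging over near-empty
classes is ill-defined, while micro pooling is stable and
permutation-invariant in the vocabulary.

## Synthetic corpus

The generator emulates the input surface, not the language: sentences are
template strings, so no NLP claim is tested.  Defaults (chosen once as the
study conditions):

| parameter | default | why |
|---|---|---|
| `n_relation_labels` | 125 | vocabulary size incl. the null label |
| `topics` | 8 LitCovid categories | the curated article-topic set |
| `not_a_relation_rate` | 0.30 | null assertions are a large minority of sentence pairs |
| `inverse_pair_fraction` | 0.20 | a minority of facts are stated in both directions |
| `probability_concentration` | 4.0 | Beta(c, 1) confidences: winner-skewed like a trained softmax |
| `attention_score_distribution` | lognormal(1, 1) | attention metrics are heavy-tailed |
| `mean_sentences_per_paper` | 12 | Poisson sentence counts per abstract-scale document |
| entity-type weights | gene .30 / chem .30 / disease .25 / species .15 | a literature-like mix |

Entity IDs use the UMLS CUI surface form (C + 7 digits; the default
target is the real COVID-19 CUI C5203670) so joins look like production
data.  Planted drug paths emit every template and qualification edge from
two distinct provenance papers, making planted structure pass the
two-text condition by construction; ground truth is recorded on the
bundle for recovery tests.  A planted drug already linked to the target
raises a conflict error rather than silently producing an invalid
negative control.

The probability distribution of a real RE model's confidences is unknown;
the Beta stand-in is a shape assumption, not a calibration.  Consequently,
passing tests demonstrate correctness of the *pipeline mechanics*
(merging, counting, scoring, enumeration, exports) under realistic data
shapes — they do not certify behavior on real model output, corpus-scale
label distributions, or entity-normalization noise beyond the
unknown-CUI fallbacks exercised here.

## Problem sizes

The test suite and the acceptance script use deliberately small problem
sizes chosen to exercise every code path while keeping runs fast and
deterministic: random graphs of 10–60 nodes (100 graphs for Adamic–Adar
oracle comparison, 50 for path-enumeration oracle comparison, 20 for
export round trips), 20 planted bundles, 200 random evaluation instances,
and corpora of 15–300 papers.  Oracle agreement is exact (< 1e-12), so
larger sizes would add runtime without adding information.

## Known limitations

* The 49/97/9-style corpus-scale path counts of a real deployment depend
  on the exact binding of a production relation vocabulary to edge
  classes; the default class map covers the synthetic vocabulary and must
  be rebound for real data.
* Aggregation assumes entity normalization upstream; near-duplicate
  entities appear as distinct nodes.
* The conclusive-language filter is keyword-based; negated conclusions
  ("did not demonstrate") are not parsed.
* PCA coordinates are only identified up to the documented sign
  convention; comparing embeddings across label universes requires the
  same union label set.
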