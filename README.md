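# relgraph

Knowledge-graph analytics for large-scale biomedical relation extraction.

Modern relation-extraction (RE) models turn a literature corpus into
millions of sentence-level assertions: *(head entity, relation, tail
entity)* triples with a softmax confidence, typed entities (gene, disease,
chemical, species) normalized to UMLS concept identifiers (CUIs), article
topics, publication dates and attention scores.  `relgraph` implements
everything that happens *after* the classifier: it is aimed at biomedical
text-mining researchers who want to turn raw RE output into a queryable
property knowledge graph and mine it for drug-repurposing candidates.

## What it computes

**Triple aggregation.** Sentence-level predictions are merged into unique
edges after removing "not a relation" records and collapsing
inverse-direction label pairs (*A may_treat B* ≡ *B may_be_treated_by A*).
Each aggregated edge carries the relation type, direction flag, the number
of distinct source papers *n*, and the mean and sum of the contributing
probabilities.  Credibility filters (publication-date window, above-mean
attention score, conclusive-language keywords) can restrict the stream
first.

**Knowledge graph + Adamic–Adar.** Nodes are typed entities; edges are
aggregated triples, exportable as Neo4j bulk-import CSVs and node-link
JSON.  Closeness of two nodes *x, y* is scored with the Adamic–Adar
statistic on the undirected projection,

    A(x, y) = Σ_{u ∈ N(x) ∩ N(y)} 1 / ln |N(u)|,

which up-weights shared neighbors that are themselves specific
(low-degree).

**Drug discovery.** An *existing* drug for a target disease must
(1) affect a gene associated with the target, (2) treat a disease
associated with the target, and (3) support every evidence edge with at
least two distinct papers.  *Novel* candidates are drugs with no direct
edge to the target that reach it through one of three typed 4-node
metapaths — a: drug→disease→gene→target, b: drug→disease←drug→target
(plus a drug–drug association), c: drug→gene→gene→target — where the
second node must itself be associated with the target.  Both result sets
are ranked by A(drug, target).

**Topic analytics.** Per-topic relation profiles (with seeded equal-paper
subsampling), top-k enrichment, pairwise topic similarity by *amount*
(Pearson correlation of relation-proportion vectors) and *diversity*
(Jaccard index of relation-presence sets), a 2-component PCA embedding of
topics, and entity-type × entity-type relation-strength matrices.

**Evaluation layer.** Row-wise softmax, weighted-average ensembling of
submodel probability matrices, support-weighted precision/recall/F1 over
the 125-label vocabulary, and micro-averaged one-vs-rest precision-recall
curves excluding the null label.

**Synthetic corpus.** A seeded generator emulates the full input surface —
125 relation labels with inverse pairs, typed entities with synthetic
CUIs, eight article topics, paper metadata — and can *plant* drug paths
with recorded ground truth, so the entire pipeline is testable offline.

## Worked example

`examples/build_graph_discover_drugs.py` generates a corpus, plants seven
drug paths and one fully evidenced existing drug, builds the graph and
runs discovery:

```
records:  2125
triples:  1278 unique (head, relation, tail) edges
graph:    225 nodes, 1278 edges
existing drugs meeting all 3 conditions: ['C8999000']
novel drug paths per pattern (unique drugs): {'a': 3, 'b': 2, 'c': 2}
top paths by Adamic-Adar score:
pattern  drug_id     mid1     mid2   target  adamic_adar
      b C8000030 C8000031 C8000032 C5203670     1.820478
      b C8000033 C8000034 C8000035 C5203670     1.820478
      a C8000000 C8000001 C8000002 C5203670     0.910239
```

The planted drugs are recovered exactly — three pattern-a, two pattern-b
and two pattern-c candidates — and the injected existing drug is the only
hit satisfying all three conditions.  Pattern-b drugs score higher here
because they share two specific intermediates with the target
(2/ln 2 ≈ 2.885 would be two degree-2 shared neighbors; these
intermediates have degree 3, giving 2/ln 3 ≈ 1.820).  Other example
scripts cover corpus simulation, sentence annotation at the five entity
levels, ensemble evaluation and topic enrichment.

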