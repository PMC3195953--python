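# interolognet

Build the protein–protein interaction (PPI) network of a query protein list —
a molecular machine and its cofactors — from heterogeneous multi-species
interaction tables, and characterise it statistically.

No single database or screen captures the interactome of a protein of
interest. This package implements a scriptable version of the
integration workflow used for chaperone-machine interactomes: mine every
available per-species interaction table, query each species network with the
protein list, project the non-human networks into the human namespace
through ortholog groups (the *interolog* concept: if two proteins interact
in one species, their identifiable human orthologs are likely to interact as
well), discard predictions already known in human, and merge everything into
one human-projected interactome `G_H` with per-edge provenance and
human-vs-predicted origin tags.

## Method

Given per-species tables of interactions (two interactor ids, taxon ids,
physical/genetic category, source database, detection method, PubMed ids):

1. **Clean** — keep physical, intra-species interactions; unify identifiers
   through a conversion map; collapse duplicate orientations onto canonical
   undirected edges with union-merged provenance; divert self-interactions
   (homodimers) out of the edge set so all graph measures have simple-graph
   semantics.
2. **Query** — extract, per species, the subgraph induced on the query
   proteins plus all first neighbors (including neighbor–neighbor, "second
   level" edges). Non-human query lists are the species' orthologs of the
   human queries.
3. **Project** — map each non-human edge (a, b) to every human pair
   (h_a, h_b) with h_a, h_b human members of the endpoints' ortholog groups
   (full cross product under one-to-many orthology); drop edges without an
   identifiable human ortholog on either side.
4. **Subtract** — remove projected candidate interologs already described in
   the human network.
5. **Merge** — union the human query network with all subtracted interolog
   networks; each edge carries an origin set ⊆ {human, interolog:taxid…}.
6. **Topology** — six graph measures: mean degree 2m/n; diameter of the
   largest connected component; index of aggregation (largest component size
   / n); connectivity (edge density 2m/(n(n−1))); mean local clustering
   coefficient (degree < 2 nodes contribute 0); assortative mixing
   coefficient (Pearson correlation of endpoint degrees over both edge
   orientations). Significance comes from a random-query null model: repeat
   the same next-neighbor extraction for many uniformly drawn query sets of
   equal size from the base network and compare each observed measure with
   the sampled distribution (add-one empirical two-sided p).
7. **Enrichment** — hypergeometric upper-tail GO over-representation of the
   network members, P(X ≥ k) for X ~ Hypergeom(N, K, n), with
   Benjamini–Hochberg (default) or Bonferroni correction, and a functional
   map: significant terms with at least 8 member proteins as nodes, edges
   between terms whose memberships agree (Cohen's kappa ≥ 0.4 by default),
   connected clusters labelled by their most significant term.

A synthetic multi-species generator (`interolognet.synthetic`) emulates all
inputs — partially overlapping interolog content via a shared ancestral edge
set, incomplete ortholog coverage, a planted densely connected query machine
and a planted enriched GO term — and records the exact merged edge set the
pipeline must reproduce, so the whole workflow is testable without
downloading anything.

## Worked example

```python
import tempfile
from interolognet.pipeline import PipelineConfig, run_pipeline
from interolognet.synthetic import FixtureSpec, generate, write_bundle

spec = FixtureSpec(seed=1)              # default synthetic study conditions
bundle = generate(spec)
with tempfile.TemporaryDirectory() as d:
    paths = write_bundle(bundle, d)
    config = PipelineConfig.from_yaml(paths["config"])
    result = run_pipeline(config)

m = result.measures
print(f"merged network: {m.n_nodes} nodes, {m.n_edges} edges")
truth = {tuple(e) for e in bundle.truth["merged_edges"]}
print("planted edge set recovered exactly:", result.merged.edge_set() == truth)
print(result.comparison[["measure", "observed", "null_mean", "z", "p"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
merged network: 340 nodes, 1051 edges
planted edge set recovered exactly: True
               measure  observed  null_mean      z     p
               n_nodes   340.000    193.580  8.766 0.003
               n_edges  1051.000    235.060 17.559 0.003
           mean_degree     6.182      2.409 12.775 0.003
              diameter     5.000     10.520 -2.939 0.013
  index_of_aggregation     1.000      0.594  4.415 0.003
          connectivity     0.018      0.012  6.133 0.003
clustering_coefficient     0.061      0.047  0.737 0.465
         assortativity    -0.169     -0.251  0.946 0.339
          n_components     1.000     18.313 -5.928 0.003
```

The merged query interactome is larger, denser and more aggregated than
random-query control networks extracted from the same base (p = 0.003 is the
floor of the add-one estimator at 300 replicates): exactly the behaviour
expected of a real molecular machine against its background database. The
enrichment stage ranks the planted GO term first
(`GO:1000001, k=83, p_adj=1.1e-10`).

Every stage is also a CLI verb over a YAML config:

```sh
interolognet fixtures make --out bundle        # synthetic inputs + truth
interolognet all --config bundle/config.yaml   # clean ... enrich
interolognet topology-tools compute --net bundle/results/merged.xgmml
```

Outputs include canonical edge tables, Cytoscape-importable XGMML/SIF with
`is_query`/`origin` attributes, tidy topology and enrichment TSVs, and a
JSON manifest with the row counts in and out of every filter.

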