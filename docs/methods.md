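# Methods

This note documents the models, conventions and design choices behind
`interolognet`, in the order the pipeline runs. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Cleaning and the canonical record

All input dialects reduce to one record: two interactor ids, two NCBI taxon
ids, a physical/genetic category, and provenance (source database, detection
method, PubMed ids). The primary dialect is an 8-column tab-delimited table;
a PSI-MI TAB 2.5 adapter maps interactor ids (columns 1–2), detection method
(7), publications (9), taxa (10–11), interaction type (12) and source
database (13) into the same record, preferring the human-readable name
inside parentheses of a `psi-mi:"MI:…"(name)` cell. Malformed rows
warn-and-skip rather than abort — real database dumps contain stray rows —
and every skip is counted in the run manifest.

Cleaning keeps physical intra-species interactions only. Identifier
unification goes through a user-supplied conversion table; a one-to-many
entry duplicates a record to every target, which is the curation mechanism
for reports that do not name a specific isoform (map the ambiguous id to
both isoform symbols). Under `strict` policy unmapped records are dropped
and counted; under `passthrough` they survive unchanged.

Graphs are simple and undirected: the canonical edge key is the
lexicographically sorted id pair, duplicate reports union-merge their
provenance, and self-interactions (homodimers) are retained as records and
exported but excluded from the edge set. Degree, clustering and
assortativity therefore always have loop-free semantics; loops would
distort them silently.

## Query networks, projection, subtraction, merge

The query network is the subgraph induced on (query ∩ nodes) ∪ N(query):
first-level interactions plus all edges among the selected nodes, so
"second level" neighbor–neighbor edges are kept. Extraction is idempotent
and every retained node is within distance 1 of a query node.

Orthology comes from a HomoloGene-style group table; a gene belongs to at
most one group (violations are a hard error). Projection of a non-human
edge emits the full cross product of the endpoints' human group members:
groups rarely contain more than one human gene, and expansion is the only
choice that loses no candidate interolog. Projected self-pairs (paralogs
collapsing onto one human gene) are dropped, consistent with the loop-free
contract. Every projected edge carries an `interolog:<taxid>` origin tag
that survives all later merges, so the human/predicted distinction remains
reconstructible in the final network.

The pipeline subtracts projected candidates against the **full** cleaned
human network, not just the human query network: "already described in
human" is a statement about all known human interactions, and subtracting
against the smaller query network would re-introduce known edges as
predictions. Stage order is extract → project → subtract → merge; projecting
the full base network first would commute only under one-to-one orthology.

Merging is a pure union of node and edge sets under canonical keys, with
origins and provenance union-merged; it is commutative and associative, and
an edge arriving both as human and as interolog keeps both origins.

## Topology and the random-query null model

Six measures on the merged network:

| measure | definition | notes |
|---|---|---|
| mean degree | 2m/n | |
| diameter | max eccentricity in the **largest component** | a disconnected network would otherwise be infinite |
| index of aggregation | largest component size / n | 1 ⟺ connected |
| connectivity | edge density 2m/(n(n−1)) | 0 by convention (flagged) for n = 1 |
| clustering coefficient | mean local coefficient over **all** nodes | degree < 2 contributes 0, so the per-node distribution is defined everywhere |
| assortativity | Pearson r of endpoint degrees over both orientations of every edge | undefined (flagged as missing, never a number) when endpoint-degree variance is 0 |

"Connectivity" is adopted as global edge density: it is listed beside mean
degree and clustering as a density-family measure, and density is the
standard third member of that family. The measure is isolated in one
function should a different convention be preferred.

The null model draws `query_size` nodes uniformly without replacement from
the base network — the disjoint union of the cleaned species networks, with
taxid-prefixed node names so symbols never collide across species — and
repeats the same next-neighbor extraction, 300 replicates by default.
Control networks are deliberately *not* interolog-projected; they
characterise what a random query list retrieves from the same underlying
data. Replicate r uses the deterministic stream `default_rng([seed, r])`,
so the distribution is a pure function of (base, query size, replicates,
seed) and any replicate can be regenerated in isolation. Internally each
replicate slices the base adjacency matrix directly; a test asserts
bit-level equivalence with the public extract-then-measure path. Diameters
of the few-hundred-node extracted subnetworks are computed exactly by
boolean reachability-power squaring with BLAS matmuls (binary search over
composed powers), falling back to sparse Dijkstra above 1024 nodes.

Comparison reports, per measure, the null mean and SD, a z-score, and the
add-one empirical two-sided p `(1 + #{|x−μ| ≥ |obs−μ|})/(reps+1)`, which
cannot return 0 from finite sampling; undefined assortativity replicates
are excluded with the exclusion count reported. Replicate query size
defaults to the real query list's length, making the controls
size-matched to the real study.

## Enrichment and the functional map

Over-representation is the hypergeometric upper tail P(X ≥ k) with
N = background universe, K = annotated-in-universe, n = members-in-universe,
k = overlap; terms with k = 0 are omitted. The default background is the
protein complement of the merged base network (every human protein plus the
human image of every non-human base protein) — the set the interaction data
could have returned — with the whole annotation as an opt-in alternative.
Benjamini–Hochberg is the default correction (Bonferroni available).
Annotations are flat sets; parent–child propagation through the ontology
graph is deliberately out of scope and should be done upstream when
preparing the annotation table.

The functional map keeps terms with adjusted p ≤ α (default 0.05) **and**
at least 8 member proteins from the network (the threshold applies to the
overlap k — proteins from the interactome — not to the term's total
annotation count). Edges join term pairs whose binary membership vectors
over the member set reach Cohen's kappa ≥ 0.4 (the convention of the
functional-grouping tools this mirrors); Jaccard is pluggable. Connected
clusters are labelled by their most significant term. Construction is
invariant to the input ordering of the results.

## Synthetic study conditions

The generator's defaults define the study conditions at desk scale and are
not tuned per test:

| parameter | default | rationale |
|---|---|---|
| species / nodes | human 800 + six species × 200 (2000 total) | seven-organism integration, human the largest table |
| background_edge_p | 0.005 | base mean degree ≈ 10, the density of large aggregated PPI collections |
| query_size | 39 | a realistic chaperone-machine query list |
| shell_size | 100 | machine + shell ≈ 7% of the base, matching the proportion a dense machine occupies |
| planted_p_in | 0.15 | extracted machine mean degree ≈ 15, the density a real machine interactome shows |
| ortholog_coverage | 0.8 | HomoloGene-like incomplete coverage |
| human_overlap_fraction | 0.3 | most projected interologs are novel, a minority already known in human |
| n_go_terms / planted_term_effect / background rate | 30 / 0.6 / 0.05 | one clearly enriched process over flat noise |

Cross-species structure: a shared "ancestral" edge set is sampled over the
human namespace (Erdős–Rényi background plus the dense machine block) and
copied into each species through the inverse ortholog map, with
species-private ER noise added. This makes projection checkable against an
explicit truth: the generator recomputes the expected merged edge set with
plain set arithmetic, sharing no code with the pipeline, and the pipeline
must reproduce it exactly. Emitted tables contain deliberate chaff (genetic
rows, cross-species rows, self-pairs, flipped orientations) that the
cleaning stages must handle.

The ER background is the default because the contracts under test
(extraction, projection, null calibration) are degree-distribution-agnostic
and ER gives closed-form expectations; a preferential-attachment option
exists for qualitatively heavy-tailed degrees. What the generator does
*not* emulate: study bias, detection-method correlation, or real ortholog
group structure — passing tests demonstrate the correctness and calibration
of the machinery, not database-specific biases of real data.

One spec detail: the generator accepts `planted_p_in == background_edge_p`
(nothing planted) because that limiting case *is* the null-calibration
condition.

## Simulation sizes and numerical choices

Null-model calibration uses 200 seeded replicate studies and power 100, on
a single 2000-node base with query size 30, each with a 99-replicate null —
99 makes the add-one p land on multiples of 1/100, so p ≤ 0.05 occurs with
probability exactly 0.05 under exchangeability. Calibration is asserted
inside the central 99.9% binomial interval; power requires rejection (p ≤
0.05 in the elevated direction) in ≥ 90% of runs for mean degree and
clustering, at the generator's default machine density. The acceptance
script re-estimates both at 100/50 seeds.

All randomness flows from a single seed: pipeline stages salt it with the
stage name (CRC32), the null model salts it with the replicate index, the
acceptance script spawns child seeds from one generator. Outputs print
floats at fixed precision (`%.6g`), so re-running a configuration is
byte-identical.

Degenerate inputs: an empty graph has no measures (error); a single-node
graph gets diameter 0 and density 0 with a `density_defined=False` flag;
an all-genetic table cleans to an empty network; queries absent from a
network are reported, not fatal.

## Known limitations

- Identifier normalisation is only as good as the supplied conversion map;
  no isoform resolution is attempted beyond one-to-many map entries.
- Orthology comes exclusively from the group table; no sequence-based
  inference.
- The published-value topology check requires the original supplementary
  XGMML network file, which is third-party data not redistributed here; the
  corresponding test fails until the file is placed locally.
- GO term hierarchy is not traversed; annotations are flat sets.
- No graph layout or visualisation beyond Cytoscape-importable exports and
  an optional null-comparison boxplot figure.
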