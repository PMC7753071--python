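# Methods

This note documents the models, defaults and numerical choices behind
`panomnet`, and what the synthetic fixtures do and do not demonstrate.

## Network model

The meta-interactome is a simple multi-layer graph: one node per gene
symbol (proteins and the genes encoding them are not distinguished),
plus miRNA and metabolite nodes, with edge kinds `ppi` (undirected,
canonical endpoint order), `mirna_target` and `tf_target` (directed),
and `enzyme_metabolite` (undirected incidence). Self-edges and
parallel edges within one kind are always dropped: the clustering
coefficient and the local-entropy definitions both assume a simple
graph. Merging the layers is a set union and therefore
order-independent; identifiers used with incompatible node kinds (the
same string as both a miRNA and a protein) abort the merge rather than
silently coercing.

The STRING reader filters on the `experimental` channel at a default
threshold of 700 (the "medium-high" confidence convention on STRING's
0–1000 scale); the combined channel is available behind an explicit
`score_column` argument. The reader filters only by score — it does
not attempt accession mapping or species filtering, which must happen
upstream.

## Omics harmonization

Primary layers (mRNA, miRNA, proteomics) decide deregulation; secondary
layers (genomics, epigenomics, phosphoproteomics, metabolomics) can
only mark nodes as altered or seed the metabolite-driven extraction.
Choices worth stating:

* **Inclusive thresholds.** `logFC >= logfc_up` (resp. `<= logfc_down`)
  and `p <= p_max`, all inclusive. Defaults ±1 and 0.05 — the
  conventional two-fold / 5% cut.
* **Per-table normalization.** The [−1, +1] rescaling divides by the
  maximum |logFC| *within the uploaded table*, not within the network,
  so the scale is a property of each dataset. An all-zero table has no
  scale and is rejected.
* **Threshold-passing records only** enter the cross-layer sum. The
  alternative (summing all normalized values) would let many weak,
  non-significant layers outvote one significant one; restricting to
  passing records keeps the per-layer significance filter meaningful.
* **Exact cancellation** (opposite signs summing to |sum| ≤ 1e-12)
  leaves the node merely expressed, mirroring the non-zero-sum rule.
* **Duplicate identifiers** keep the record with the smallest p-value.

## Extraction

Seeds are the up/down/altered nodes mapped onto the network; expansion
is breadth-limited (1 or 2 hops) across *all* edge kinds and traverses
regulatory edges against their direction too, so a deregulated target
pulls in its regulators. The result is the induced subgraph on the
reached nodes — edges between two non-seed neighbors are kept.
Metabolomics-driven extraction seeds the enzymes incident to listed
metabolites, expands one protein hop, and keeps only the listed
metabolites as leaves.

## Topology indices and TIN selection

Centralities are computed with networkx on the undirected projection:
degree (raw neighbor count), betweenness normalized by (N−1)(N−2)/2,
component-scaled (Wasserman–Faust) closeness, and the triangle
clustering coefficient. Each index is max-rescaled and z-scored with
the sample SD (ddof = 1) over the candidate set; since both transforms
are affine, z-scores on raw and rescaled indices are identical — the
rescaled values are still reported because they are the interpretable
"fraction of the maximum" quantity.

The cumulative centrality score includes the node's own combined score
in addition to the first-layer sum, CCS(i) = c(i) + Σ_{j∈N(i)} c(j);
without the self term isolated candidates would all tie at zero and be
unrankable. A combined-score component that is uniformly zero across
the network (clustering in a triangle-free graph, betweenness in a
complete graph) contributes zeros rather than raising the
normalization error that the standalone rescaler reports.

Selection is strictly greater-than on the z-threshold (default 1.0 for
all three families when run non-interactively). The interactive
threshold choice of a web workflow is replaced by a two-pass CLI: the
first pass writes the z-score density histograms (TSV, optional PNG),
the second accepts thresholds. IINs require membership in ≥ 2 of the
three TIN families. Degenerate z-distributions (constant index over
candidates) are a hard error: no threshold can separate anything.

## Enrichment

Both hypergeometric forms are computed for every pathway with non-zero
overlap: the single-table point probability C(b,a)·C(d,c)/C(b+d,a+c)
(evaluated in log-gamma space; agrees with exact rational arithmetic to
1e-12 over the exhaustively swept small domain) and the one-sided
over-representation tail under the law with population d, successes c,
draws b. The point form uses the full query size b even when query
genes fall outside the pathway universe; the tail form, whose sampling
model draws from the universe, uses draws = |query ∩ universe|
(draws > population is undefined). Selection defaults to the raw tail
p ≤ 0.05 (inclusive); Benjamini–Hochberg correction is available but
off by default, matching the common practice for this style of
pathway screen. Prognostic-marker joins report the minimum-p cancer
type first and retain all rows.

## Cross-pathway path scoring

The enumeration is an exhaustive depth-first search for simple paths
of ≤ 4 PPI edges from each entry point X (signaling proteins, or
targets of deregulated TFs/miRNAs with the regulator recorded as a
path prefix) to any metabolic enzyme, in deterministic lexicographic
order. The filter demands deregulated terminals — in regulatory modes
the regulator itself, judged by its own omics layer, and the enzyme —
and at-least-expressed interiors; "expressed" means covered by a
primary omics layer.

The score is a log-likelihood with two ingredient families:

* **Transitions.** s(v) = 1 + |combined normalized logFC(v)| ∈ [1, 1+k]
  for k primary layers; the step u→v gets probability
  s(u)s(v) / Σ_{u′ eligible} s(u)s(u′), normalized over u's
  expressed-or-deregulated neighbors of the step's edge kind, so each
  node's outgoing mass sums to one. The additive-one baseline keeps
  every product positive and gives merely expressed nodes a neutral
  score of 1.
* **Emissions.** e(v) = (1 + w(v) + [entropy]·H(v)/H_max) / (2 + |W|),
  with w(v) the count of satisfied selected weight options (six
  available, at most four selectable: deregulated gene, crosstalk
  gene, rate-limiting enzyme, hub, central node, bottleneck), and H(v)
  the local Shannon entropy of the eligible-neighbor weight profile,
  rescaled by the network maximum and included only when the entropy
  flag is on (it is an extra ingredient, not one of the six options).
  The denominator bounds e(v) in (0, 1], so the path score is finite,
  monotone in every node weight, and comparable across paths of equal
  length.

This emission/transition contract is this package's own concrete
instantiation of the qualitative recipe (node weights + normalized
interaction probabilities + z ≥ 1 selection); the denominator constant
is exposed through the code rather than a config file because no
sensible alternative presented itself. Path scores are standardized
over all filtered paths of the run (ddof = 1) and the inclusive z ≥ 1
rule selects the important paths. A two-stage variant — scoring X–M
*pairs* first and then re-scoring paths within important pairs — is
deliberately not implemented: the pair-level score has no defined
form, so the package scores paths globally.

## Synthetic data

The generator emulates the input formats end to end: a
Barabási–Albert(m = 2) PPI layer over 200 proteins by default
(Erdős–Rényi optional), 20 miRNAs and 10 TFs wired to ≤ 8 random
targets each, 30 metabolites attached to a 20% enzyme subset, 20%
signaling proteins, plus crosstalk / rate-limiting annotation lists.
Omics tables plant ~20% deregulated nodes at |logFC| ~ N(2.0, 0.3) and
p ~ U(0, 0.049) against a sub-threshold expressed background, and one
planted pathway draws 70% of its members from the planted deregulated
genes. Ground truth is written beside the tables, and everything is a
pure function of one integer seed.

What the fixtures do *not* emulate: real degree distributions beyond
the scale-free option, correlated noise between omics layers,
identifier mapping artifacts, or pathway overlap structure. Passing
the recovery tests therefore demonstrates algorithmic correctness
(the planted signal is found when the model assumptions hold), not
performance on real cohorts.

Problem sizes used by the test suite and the acceptance script — the
200-protein default fixture, all connected graphs on ≤ 7 nodes for the
centrality sweep, 200 random ≤ 8-node graphs for path enumeration,
b+d ≤ 14 / d ≤ 12 for the exhaustive hypergeometric sweeps, and 60–100
fixture replicates for the recovery rates — were chosen so every check
is exhaustive or statistically stable at desk scale.

## Known limitations

* One node per gene symbol: isoforms, complexes and accession synonyms
  must be resolved upstream.
* The hop-bounded path search is exhaustive, so dense networks with
  many eligible entry points can produce large path sets; the bound of
  three intermediates is structural, not a performance guard.
* The betweenness/closeness definitions ignore regulatory edge
  direction (the undirected projection), consistent with treating the
  filtered network as an interaction map rather than a flow network.
* Enrichment treats pathways independently; genes in many pathways are
  counted in each.
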