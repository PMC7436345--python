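# Methods

This note documents the statistical and graph-theoretic choices behind each
pipeline stage, the synthetic-data model used to exercise them, and the
known limitations of both.

## ADME screening

Compounds are retained when oral bioavailability OB ≥ `ob_min` (default 30,
percent) **and** drug-likeness DL ≥ `dl_min` (default 0.18, dimensionless in
[0, 1]). Both comparisons are inclusive, matching the usual "≥ 30% / ≥ 0.18"
convention of TCMSP-style screening. The filter is order-preserving,
monotone in both thresholds, and idempotent. The packaged SXD catalog is
shipped verbatim, including one row (Baicalin, OB 29.53) that sits below the
OB cutoff while appearing in the published 67-compound table; the pipeline
reports both the raw count and the strictly filtered count and flags the
difference as a warning instead of patching the data.

## Gene-symbol handling

Symbols are opaque canonical tokens: trimmed and uppercased, nothing more.
No alias, ortholog or probe resolution is attempted; inputs are expected to
use one consistent nomenclature. Target maps deduplicate (compound, gene)
pairs after canonicalization; a compound catalogued under several herbs
keeps multi-herb membership and is additionally reported in a "shared"
group.

## Differential expression

Per gene, the effect is the difference of group means on log2-scale data
(so it is a log2 fold change); significance is a two-sided Welch *t*-test
(unequal variances, Welch–Satterthwaite df). Welch was chosen over a
moderated-variance model because it is exactly specified, assumption-light,
and trivially cross-checkable against the closed-form statistic; the
thresholding logic consumes only (log2FC, *P*) pairs, so a different test
can be substituted upstream. Degenerate rows with zero variance in both
groups get *P* = 1 when the group means are equal and *P* = 0 otherwise.
Each group must have ≥ 2 samples.

Calls use *P* < `p_max` (default 0.05) and |log2FC| > `lfc_min` (default
0.5), both strict, matching common volcano-plot practice. BH-adjusted
*P*-values are always computed and written; they gate the calls only when
`adjust` is enabled, since raw-*P* thresholding is the norm in the
microarray literature this pipeline emulates.

## PPI construction and the two-stage hub screen

The interactome is grown from the common-target seeds by **one-hop
expansion with induced closure**: seeds present in the background, their
direct interactors, and every background edge among those nodes. Self-loops
and duplicate edges are dropped; the graph is simple and undirected.

Six centralities are computed from their definitions:

* **DC** — degree.
* **BC** — betweenness as raw shortest-path pair counts (unnormalized,
  unordered pairs), the scale CytoNCA-style tools report.
* **CC** — closeness within the node's connected component,
  (|C|−1)/Σd; isolated nodes get 0.
* **EC** — the entrywise non-negative dominant adjacency eigenvector,
  L2-normalized, by power iteration from an all-ones start (tolerance
  1e−10 on the max component change, cap 10⁴ iterations). Iteration uses
  the +I shift — identical eigenvectors, but plain iteration cannot
  converge on bipartite graphs, where +λmax and −λmax tie in magnitude.
* **LAC** — mean, over neighbors u of v, of u's degree inside the subgraph
  induced by N(v); 0 for isolated nodes.
* **NC** — sum over incident edges of the edge clustering coefficient
  ECC(v,u) = z/min(d_v−1, d_u−1), z = triangles through the edge. ECC is
  defined as 0 when the denominator is non-positive; the z+1 numerator
  variant is available (`ecc_plus_one`) but off by default.

The screen: stage 1 keeps nodes with DC ≥ `stage1_multiplier` × median DC
(default multiplier 2; inclusive, switchable to strict) and takes the
induced subgraph; stage 2 recomputes all six centralities **on that
subgraph** and keeps nodes strictly exceeding all six medians. Recomputation
rather than reuse reflects how such screens report "medians in this
network". Medians average the two middle order statistics for even counts.
The screen is fully deterministic, and core ⊆ stage1 ⊆ nodes always holds;
strict stage-2 comparison guarantees the core is a proper subset whenever
stage 1 is non-empty.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) with
population N (the collection background), K term members, n query genes in
the background, and overlap k. The tail is accumulated in log space
(logsumexp of log-pmf terms) for stability at extreme parameters. An EASE
variant (k−1 in the tail, the conservative DAVID-style score) is available
behind a flag; the plain tail is the default because it is exactly
specifiable. FDR is Benjamini–Hochberg. Rows with FDR < `fdr_max` (default
0.05) are sorted by (FDR, *P*, term id) — a fully deterministic tie-break —
and truncated to `top_k` (default 20). GeneRatio is k/n. The background
defaults to the union of all term members and can be widened to a user
universe; query genes outside the background are dropped before testing.

Note that BH adjustment is *not* idempotent (re-adjusting adjusted values
inflates them further); the implementation is tested against the hand-worked
step-up example and the true invariants (order invariance, pointwise
dominance of the input, cap at 1).

## Bipartite networks

The compound–target network keeps compounds with ≥ 1 common target on the
left and the common targets on the right; the gene–pathway network connects
member genes to their top-k pathways. Degree rankings are descending with
lexicographic tie-break, so runs are reproducible; a tie at the top
("core gene") is reported explicitly as a warning. GraphML exports carry
role/herb/category attributes and round-trip losslessly.

## Synthetic data model

Each generator is deterministic given `SimConfig.seed` (one seed fans out
to per-stage substreams, so stages regenerate independently) and returns a
truth record alongside the data. Quantities that downstream checks compare
exactly are constructed, not sampled.

* **Catalog** — exactly ⌈`adme_pass_fraction`·n⌉ compounds pass both ADME
  cutoffs; the rest fail OB, DL, or both. Defaults: 100 compounds across
  three herbs, pass fraction 0.67.
* **Target map** — per-compound target counts follow a Zipf(1.6) draw
  (capped at a quarter of the pool), mimicking the promiscuous-hub
  character of real compound-target data.
* **Expression** — per-gene baselines ~ N(8, 1) on the log2 scale; planted
  genes (default 200 of 5000) shift case means by ±1.0 log2 units (half up,
  half down); i.i.d. N(0, 0.4) noise; 12 case + 12 control samples,
  mirroring the 24-sample two-group cohort the pipeline emulates. At these
  settings the Welch test's planted-effect recall is essentially 1 and its
  null false-positive rate matches the nominal level.
* **PPI background** — a Barabási–Albert graph (default 400 nodes, m = 2)
  whose node labels are gene symbols; a planted hub set (default 12) is
  made a clique and each hub is wired to a *disjoint* block of 8% of all
  nodes. Disjoint spokes ensure bystanders carry at most one hub edge and
  no hub-induced triangles, so the planted hubs are the only nodes pairing
  high degree with high neighborhood clustering — the joint signal the
  two-stage screen selects for.
* **Gene sets** — decoy terms drawn uniformly from the gene universe plus
  planted terms overlapping the query list in exactly
  `planted_term_overlap` genes (default 15).
* **Bundle** — the generators are coordinated so that exactly
  `n_common_planted` (default 37) planted DEGs are also compound targets
  and no other planted DEG is, making the expected common-target set exact;
  all common genes are guaranteed PPI-background nodes, and the pathway
  collection plants 20 terms over them so the gene–pathway stage has a
  non-trivial top-20.

### What the synthetic model does not capture

No probe-level effects, normalization artifacts, batch structure, or
correlated noise in expression; no literature curation bias or
database-version drift in targets and interactions; the m = 2 background is
far sparser than a real merged interactome (median degree ~3 vs ~20).
Passing tests therefore demonstrate algorithmic correctness and planted-
structure recovery, not robustness to real-data pathologies.

A consequence of the sparse background: the stage-2 medians sit low, and
the six-way joint cut admits a few organic mid-degree nodes alongside the
planted hubs. At the documented screen conditions (400 nodes, m = 2, 12
hubs) recall of planted hubs is 1.0 and the non-planted fraction of the
core is ~0.2, but the latter varies by seed (roughly 0.2–0.5); on denser
backgrounds the cut is much cleaner. Similarly, when the screen is run
inside the full pipeline it operates on the one-hop neighborhood of the
common targets, where planted hubs keep only part of their wiring, so
end-to-end hub recovery is attenuated relative to screening the full
background.

## Problem sizes

Defaults were chosen as desk-scale stand-ins for the emulated study: 5000
genes (vs a ~25k-probe array), 400-node interactome background (vs ~1900
nodes one-hop from 37 seeds), 200 gene-set terms. All tests and the
acceptance script run in seconds at these sizes.
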