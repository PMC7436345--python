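# netpharm

An offline network-pharmacology pipeline for multi-herb formulas. Given an
ingredient catalog with ADME scores, a compound→target map, a two-group gene
expression matrix, a background protein–protein interactome, and GO/KEGG-style
gene-set collections, it answers the standard chain of questions: which
compounds are pharmacologically active, which disease-relevant genes do they
hit, which of those genes are topological hubs of the interactome, and which
biological processes and pathways do they concentrate in.

The packaged example is *Sanhuang Xiexin* decoction (SXD), a three-herb
formula (Dahuang, Huanglian, Huangqin) studied against type 2 diabetes: the
shipped catalog transcribes its 67 published ingredients with oral
bioavailability (OB) and drug-likeness (DL) scores. Everything downstream of
the catalog can be generated synthetically with planted ground truth, so the
entire analysis runs and is testable without touching TCMSP, DrugBank, GEO,
or any web service.

## The pipeline

1. **ADME screen** — keep compounds with OB ≥ 30% and DL ≥ 0.18 (inclusive).
2. **Target mapping** — union of per-compound target sets, deduplicated;
   gene symbols are canonicalized (trim + uppercase).
3. **Differential expression** — per-gene log2 fold change
   (case mean − control mean on log2 data) with a two-sided Welch *t*-test;
   genes with *P* < 0.05 and |log2FC| > 0.5 are called up/down.
   Benjamini–Hochberg adjusted *P* is always computed.
4. **Common targets** — drug-target set ∩ disease DEG set, with per-compound
   provenance, visualized as a compound–target bipartite network.
5. **PPI hub screen** — grow a network from the common targets by one-hop
   expansion against the background interactome, then screen in two stages:
   (i) keep nodes with degree ≥ 2 × median degree; (ii) on that induced
   subgraph recompute six centralities — degree (DC), betweenness (BC,
   unnormalized), closeness (CC), eigenvector (EC), local average
   connectivity (LAC), and edge-clustering/neighborhood centrality (NC) —
   and keep the nodes strictly above all six medians. These are the *core
   genes*.
6. **Enrichment** — hypergeometric upper-tail over-representation
   P(X ≥ k), X ~ Hypergeom(N, K, n), BH-FDR across terms, FDR < 0.05,
   top 20 by (FDR, *P*, term id); GeneRatio = k/n.
7. **Gene–pathway network** — membership bipartite network over the top
   pathways; the maximum-degree gene is the *core gene*.

## Worked example

```sh
netpharm filter-compounds src/netpharm/data/table1_sxd.tsv
```

```
67 records, 66 pass the ADME screen
  Dahuang: 16
  Huanglian: 14
  Huangqin: 36
```

(The catalog ships one below-cutoff row — Baicalin, OB 29.53, under
Huangqin — which the strict screen excludes; pipeline reports flag the
67-vs-66 discrepancy rather than silently editing the table. The raw
per-herb counts of the table are 16/14/37.)

A full synthetic run:

```sh
netpharm simulate --seed 5 --out inputs/
netpharm run-all --config config.yaml --out run/ --seed 5
```

prints (abridged):

```json
{
 "compounds_active": 67,
 "targets": 2368,
 "deg": {"n_up": 107, "n_down": 107, "n_ns": 4786, "n_genes": 5000},
 "common_targets": 47,
 "ppi_nodes": 196,
 "core_genes": 12,
 "core_gene": "G01437"
}
```

meaning: 67 of 100 synthetic compounds pass the screen, their 2368 distinct
targets intersect the called DEGs in 47 genes (37 were planted; the excess
are chance intersections of false-positive DEG calls with the large target
union), the one-hop PPI network around those genes contains 196 nodes, the
two-stage screen keeps 12 core genes, and `G01437` has the highest degree
in the gene–pathway network.
Every artifact (DEG table, volcano plot, GraphML networks, centrality
tables, enrichment tables, dot plot, JSON run report) is written under
`run/`.

The library mirrors the CLI one-to-one (`filter_adme`, `compute_deg`,
`two_stage_screen`, `enrich`, `build_gene_pathway`, ...); see the module
docstrings.

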