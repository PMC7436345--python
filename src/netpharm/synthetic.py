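"""Synthetic input generators with planted, bookkept ground truth.

Every upstream data source the pipeline consumes has a generator here, so
the full analysis is exercisable and testable offline:

* a TCMSP-style herb-ingredient catalog with a controlled fraction of
  compounds passing the OB/DL activity screen;
* a DrugBank-style compound-target map with heavy-tailed (Zipf-like)
  per-compound target counts, mimicking promiscuous compounds such as
  quercetin;
* a two-group microarray-style log2 expression matrix (12 case + 12 control
  samples by default, matching the published cohort's 24-sample design)
  with planted up/down fold changes and Gaussian noise;
* a preferential-attachment interactome background in which a designated
  hub set is densified into a near-clique and wired to 10% of all nodes, so
  the hub screen has a known answer;
* GO/KEGG-style gene-set collections in which planted terms overlap the
  query list in an exact, configured number of genes.

All generators are deterministic given ``SimConfig.seed``: one global seed
fans out to independent per-stage substreams keyed by stage index, so any
stage can be regenerated without the others. Planted quantities that
downstream tests compare exactly (pass counts, overlap sizes, target
unions) are constructed, not sampled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .compounds import CompoundRecord
from .diffexpr import ExpressionMatrix
from .enrichment import GeneSetCollection
from .errors import ConfigError
from .targets import TargetMap

__all__ = [
    "SimConfig",
    "gene_universe",
    "gen_compound_catalog",
    "gen_target_map",
    "gen_expression",
    "gen_background_ppi",
    "gen_gene_sets",
    "gen_bundle",
    "SyntheticBundle",
]

# substream indices: one per generator stage
_STAGE_CATALOG, _STAGE_TARGETS, _STAGE_EXPR, _STAGE_PPI, _STAGE_SETS = range(5)

# fraction of all background nodes each planted hub is wired to; spoke sets
# are disjoint across hubs so bystander nodes receive at most one hub edge
HUB_WIRING_FRACTION = 0.08


@dataclass(frozen=True)
class SimConfig:
    """Knobs for every synthetic input source.

    Defaults mirror the published study's scale where it is known (three
    herbs at 16/14/37 active compounds, 24 expression samples, a 37-gene
    common-target overlap) and desk-scale stand-ins elsewhere (5000 genes
    for the ~25k-probe array, a 400-node interactome background).
    """

    seed: int = 0
    n_compounds_per_herb: dict[str, int] = field(
        default_factory=lambda: {"Dahuang": 24, "Huanglian": 21, "Huangqin": 55})
    adme_pass_fraction: float = 0.67
    n_genes: int = 5000
    n_per_group: int = 12
    n_deg_planted: int = 200
    effect_delta: float = 1.0     # log2 units
    noise_sd: float = 0.4         # log2 units
    ppi_n_nodes: int = 400
    ppi_attach_m: int = 2
    planted_hub_count: int = 12
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 50)
    planted_term_overlap: int = 15
    n_common_planted: int = 37

    def __post_init__(self) -> None:
        errors = []
        if any(n <= 0 for n in self.n_compounds_per_herb.values()):
            errors.append("compound counts must be positive")
        if not 0 <= self.adme_pass_fraction <= 1:
            errors.append("adme_pass_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            errors.append("noise_sd must be > 0")
        for name in ("n_genes", "n_per_group", "ppi_n_nodes", "ppi_attach_m",
                     "planted_hub_count", "n_terms"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.ppi_attach_m >= self.ppi_n_nodes:
            errors.append("ppi_attach_m must be < ppi_n_nodes")
        if self.n_deg_planted < 0 or self.n_deg_planted > self.n_genes:
            errors.append("n_deg_planted must be in [0, n_genes]")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            errors.append("term_size_range must be a non-empty ascending pair")
        if errors:
            raise ConfigError(errors)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def gene_universe(c: SimConfig) -> list[str]:
    """The shared synthetic gene-symbol universe, G00001..G<n_genes>."""
    return [f"G{i:05d}" for i in range(1, c.n_genes + 1)]


def gen_compound_catalog(c: SimConfig) -> list[CompoundRecord]:
    """Catalog with exactly ceil(adme_pass_fraction * n) screen-passing rows.

    Passing rows draw OB from U(30, 110) and DL from U(0.18, 0.9); failing
    rows fail OB, DL, or both, with values strictly below the cutoffs.
    """
    rng = c.rng(_STAGE_CATALOG)
    herbs = [h for h, n in sorted(c.n_compounds_per_herb.items()) for _ in range(n)]
    n = len(herbs)
    n_pass = math.ceil(c.adme_pass_fraction * n)
    passes = np.zeros(n, dtype=bool)
    passes[rng.permutation(n)[:n_pass]] = True
    records = []
    for i, herb in enumerate(herbs):
        if passes[i]:
            ob = float(rng.uniform(30.0, 110.0))
            dl = float(rng.uniform(0.18, 0.9))
        else:
            mode = rng.integers(3)  # 0: fail OB, 1: fail DL, 2: fail both
            ob = float(rng.uniform(5.0, 29.9)) if mode != 1 else float(rng.uniform(30.0, 110.0))
            dl = float(rng.uniform(0.01, 0.17)) if mode != 0 else float(rng.uniform(0.18, 0.9))
        records.append(CompoundRecord(
            mol_id=f"MOLS{i + 1:04d}", name=f"compound-{i + 1:04d}",
            ob=round(ob, 2), dl=round(dl, 2), herb=herb))
    return records


def gen_target_map(c: SimConfig,
                   compounds: list[CompoundRecord],
                   target_pool: list[str] | None = None,
                   must_include: set[str] | None = None,
                   ) -> tuple[TargetMap, dict]:
    """Compound-target map with Zipf-like per-compound target counts.

    ``target_pool`` defaults to the shared gene universe; every gene in
    ``must_include`` is guaranteed to be hit by at least one compound. The
    truth dict records each compound's target set and the exact union.
    """
    rng = c.rng(_STAGE_TARGETS)
    if target_pool is None:
        target_pool = gene_universe(c)
    pool = np.array(sorted(target_pool))
    tm = TargetMap()
    per_compound: dict[str, list[str]] = {}
    for rec in compounds:
        herbs = tm.herb_of.setdefault(rec.mol_id, set())
        herbs.add(rec.herb)
        if rec.mol_id in per_compound:
            continue  # same compound under a second herb: same target set
        k = int(min(rng.zipf(1.6), max(2, len(pool) // 4)))
        targets = rng.choice(pool, size=min(k, len(pool)), replace=False)
        per_compound[rec.mol_id] = sorted(str(t) for t in targets)
        for t in per_compound[rec.mol_id]:
            tm.edges.add((rec.mol_id, t))
    if must_include and per_compound:
        mols = sorted(per_compound)
        for gene in sorted(must_include):
            mol = mols[int(rng.integers(len(mols)))]
            if gene not in per_compound[mol]:
                per_compound[mol].append(gene)
                per_compound[mol].sort()
                tm.edges.add((mol, gene))
    union = sorted({g for targets in per_compound.values() for g in targets})
    truth = {"per_compound": per_compound, "union": union, "union_size": len(union)}
    return tm, truth


def gen_expression(c: SimConfig) -> tuple[ExpressionMatrix, dict]:
    """Two-group log2 expression with planted fold changes.

    Baseline means are N(8, 1) per gene; the first half of the planted genes
    shift case means by +effect_delta, the second half by -effect_delta;
    i.i.d. N(0, noise_sd) noise everywhere. Truth lists planted genes with
    their direction.
    """
    rng = c.rng(_STAGE_EXPR)
    genes = gene_universe(c)
    n = c.n_per_group
    samples = [f"control_{i + 1:02d}" for i in range(n)] + \
              [f"case_{i + 1:02d}" for i in range(n)]
    group_of = {s: ("control" if s.startswith("control") else "case") for s in samples}
    baseline = rng.normal(8.0, 1.0, size=c.n_genes)
    values = np.tile(baseline[:, None], (1, 2 * n))
    planted_idx = rng.choice(c.n_genes, size=c.n_deg_planted, replace=False)
    half = c.n_deg_planted // 2
    up_idx, down_idx = planted_idx[:half], planted_idx[half:]
    values[up_idx, n:] += c.effect_delta
    values[down_idx, n:] -= c.effect_delta
    values += rng.normal(0.0, c.noise_sd, size=values.shape)
    truth = {"up": sorted(genes[i] for i in up_idx),
             "down": sorted(genes[i] for i in down_idx)}
    truth["all"] = sorted(truth["up"] + truth["down"])
    matrix = ExpressionMatrix(genes=genes, samples=samples,
                              values=values, group_of=group_of)
    return matrix, truth


def gen_background_ppi(c: SimConfig,
                       include_genes: set[str] | None = None,
                       ) -> tuple[list[tuple[str, str]], dict]:
    """Preferential-attachment interactome with a planted dense hub set.

    A Barabasi-Albert graph (attach ``ppi_attach_m`` edges per new node) is
    relabeled with gene symbols; ``planted_hub_count`` nodes are made a
    clique and each wired to a disjoint block of ``HUB_WIRING_FRACTION`` of
    all nodes. Disjoint spokes keep bystander nodes at <=1 hub edge, so the
    planted hubs are the only nodes pairing high degree with high
    neighborhood clustering. Genes in ``include_genes`` are guaranteed node
    labels. Truth carries the hub labels and exact edge bookkeeping.
    """
    import networkx as nx

    rng = c.rng(_STAGE_PPI)
    n, m = c.ppi_n_nodes, c.ppi_attach_m
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31 - 1)))
    base_edges = g.number_of_edges()  # = m * (n - m)

    universe = gene_universe(c)
    include = sorted(include_genes or [])
    if len(include) > n:
        raise ConfigError("include_genes larger than ppi_n_nodes")
    others = [x for x in universe if x not in set(include)]
    extra = rng.choice(len(others), size=n - len(include), replace=False)
    labels = include + [others[i] for i in sorted(extra)]
    order = rng.permutation(n)
    mapping = {i: labels[order[i]] for i in range(n)}
    g = nx.relabel_nodes(g, mapping)

    nodes = sorted(g.nodes())
    hub_pick = rng.choice(n, size=c.planted_hub_count, replace=False)
    hubs = sorted(nodes[i] for i in hub_pick)
    for i, u in enumerate(hubs):          # near-clique densification
        for v in hubs[i + 1:]:
            g.add_edge(u, v)
    n_wire = round(HUB_WIRING_FRACTION * n)
    non_hubs = [v for v in nodes if v not in set(hubs)]
    shuffled = [non_hubs[i] for i in rng.permutation(len(non_hubs))]
    for i, u in enumerate(hubs):   # disjoint spoke blocks, one per hub
        for v in shuffled[i * n_wire:(i + 1) * n_wire]:
            g.add_edge(u, v)
    g.remove_edges_from(nx.selfloop_edges(g))

    edges = sorted(tuple(sorted(e)) for e in g.edges())
    truth = {"hubs": hubs, "n_nodes": g.number_of_nodes(),
             "n_edges": len(edges), "base_edges": base_edges,
             "planted_extra_edges": len(edges) - base_edges}
    return edges, truth


def gen_gene_sets(c: SimConfig,
                  target_list: set[str],
                  category: str = "pathway",
                  n_planted: int = 1,
                  ) -> tuple[GeneSetCollection, dict]:
    """Decoy terms plus planted terms with an exact target-list overlap.

    Decoy members are drawn uniformly from the gene universe; each planted
    term contains exactly ``planted_term_overlap`` genes from
    ``target_list`` plus filler genes from outside it.
    """
    rng = c.rng(_STAGE_SETS)
    if not target_list:
        raise ConfigError("target_list must be non-empty")
    if c.planted_term_overlap > len(target_list):
        raise ConfigError("planted_term_overlap exceeds the target list size")
    universe = np.array(gene_universe(c))
    targets = np.array(sorted(target_list))
    outside = np.array(sorted(set(universe) - set(targets)))
    lo, hi = c.term_size_range
    terms: dict[str, tuple[str, str, set[str]]] = {}
    for i in range(c.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = {str(x) for x in rng.choice(universe, size=size, replace=False)}
        tid = f"{category.upper()}D{i + 1:04d}"
        terms[tid] = (f"decoy {category} term {i + 1}", category, members)
    planted_ids = []
    for i in range(n_planted):
        hit = {str(x) for x in rng.choice(targets, size=c.planted_term_overlap,
                                          replace=False)}
        size = int(rng.integers(max(lo, c.planted_term_overlap), hi + 1))
        fill = {str(x) for x in rng.choice(outside, size=size - len(hit),
                                           replace=False)}
        tid = f"{category.upper()}P{i + 1:04d}"
        terms[tid] = (f"planted {category} term {i + 1}", category, hit | fill)
        planted_ids.append(tid)
    coll = GeneSetCollection(terms=terms, background=set(map(str, universe)))
    truth = {"planted_terms": planted_ids, "overlap": c.planted_term_overlap}
    return coll, truth


@dataclass
class SyntheticBundle:
    """All pipeline inputs generated coherently from one SimConfig."""

    config: SimConfig
    catalog: list[CompoundRecord]
    target_map: TargetMap
    expression: ExpressionMatrix
    ppi_edges: list[tuple[str, str]]
    go_sets: GeneSetCollection
    kegg_sets: GeneSetCollection
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text pipeline inputs; returns the paths."""
        from .enrichment import write_gmt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {k: outdir / v for k, v in {
            "catalog": "catalog.tsv", "targets": "targets.tsv",
            "expression": "expression.tsv", "groups": "groups.tsv",
            "ppi_background": "ppi_background.tsv",
            "gene_sets_go": "go.gmt", "gene_sets_kegg": "kegg.gmt",
            "truth": "truth.json"}.items()}
        with paths["catalog"].open("w") as fh:
            fh.write("mol_id\tname\tob\tdl\therb\n")
            for r in self.catalog:
                fh.write(f"{r.mol_id}\t{r.name}\t{r.ob}\t{r.dl}\t{r.herb}\n")
        with paths["targets"].open("w") as fh:
            fh.write("mol_id\tgene_symbol\therb\n")
            for mol, gene in sorted(self.target_map.edges):
                for herb in sorted(self.target_map.herb_of.get(mol, {""})) or [""]:
                    fh.write(f"{mol}\t{gene}\t{herb}\n")
        m = self.expression
        with paths["expression"].open("w") as fh:
            fh.write("gene\t" + "\t".join(m.samples) + "\n")
            for i, gene in enumerate(m.genes):
                row = "\t".join(f"{x:.5f}" for x in m.values[i])
                fh.write(f"{gene}\t{row}\n")
        with paths["groups"].open("w") as fh:
            fh.write("sample\tgroup\n")
            for s in m.samples:
                fh.write(f"{s}\t{m.group_of[s]}\n")
        with paths["ppi_background"].open("w") as fh:
            fh.write("gene_a\tgene_b\n")
            for u, v in self.ppi_edges:
                fh.write(f"{u}\t{v}\n")
        write_gmt(self.go_sets, paths["gene_sets_go"])
        write_gmt(self.kegg_sets, paths["gene_sets_kegg"])
        with paths["truth"].open("w") as fh:
            json.dump(self.truth, fh, indent=1, default=list)
        return paths


def gen_bundle(c: SimConfig) -> SyntheticBundle:
    """Generate a coherent input bundle with a planted common-target overlap.

    The planted differentially expressed genes include exactly
    ``n_common_planted`` genes that are also compound targets, and no other
    target gene is planted as a DEG — so intersecting the drug-target union
    with the planted DEG set yields exactly the configured common-target
    count. The PPI background contains every planted common gene; the
    gene-set collections plant terms overlapping the common genes.
    """
    catalog = gen_compound_catalog(c)
    expression, deg_truth = gen_expression(c)
    planted = set(deg_truth["all"])
    if c.n_common_planted > len(planted):
        raise ConfigError("n_common_planted exceeds n_deg_planted")
    rng = np.random.default_rng([c.seed, 99])
    common = {str(x) for x in rng.choice(sorted(planted),
                                         size=c.n_common_planted, replace=False)}
    pool = sorted((set(gene_universe(c)) - planted) | common)
    from .compounds import filter_adme
    active = filter_adme(catalog)
    tm, tm_truth = gen_target_map(c, active, target_pool=pool, must_include=common)
    ppi_edges, ppi_truth = gen_background_ppi(c, include_genes=common)
    go, go_truth = gen_gene_sets(c, common, category="go_bp", n_planted=3)
    kegg, kegg_truth = gen_gene_sets(c, common, category="kegg", n_planted=20)
    truth = {"deg": deg_truth, "common_targets": sorted(common),
             "target_map": tm_truth, "ppi": ppi_truth,
             "go": go_truth, "kegg": kegg_truth,
             "config": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(c).items()}}
    return SyntheticBundle(config=c, catalog=catalog, target_map=tm,
                           expression=expression, ppi_edges=ppi_edges,
                           go_sets=go, kegg_sets=kegg, truth=truth)
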