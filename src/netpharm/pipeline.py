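"""End-to-end orchestration: config validation, stage sequencing, run report.

``run_all`` executes the seven analysis stages in a fixed order — compound
screening, target mapping, differential expression, compound-target network,
PPI construction + two-stage hub screen, GO/KEGG over-representation, and
the gene-pathway network — writing every artifact (TSV tables, GraphML/SIF
networks, figures, JSON report) into the output directory and returning a
:class:`RunReport` whose fields are the pipeline's summary quantities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from . import bipartite, compounds, diffexpr, enrichment, ppi, targets
from .errors import ConfigError, NetpharmError

__all__ = ["RunConfig", "RunReport", "validate_config", "run_all"]

log = logging.getLogger("netpharm")

_DEFAULTS: dict[str, Any] = {
    # input paths (None = stage inputs must be provided another way)
    "catalog": None, "targets": None, "expression": None, "groups": None,
    "ppi_background": None, "gene_sets_go": None, "gene_sets_kegg": None,
    # thresholds, defaulting to the standard screening values
    "ob_min": 30.0, "dl_min": 0.18,
    "p_max": 0.05, "lfc_min": 0.5, "adjust": False,
    "stage1_multiplier": 2.0, "stage1_strict": False, "ecc_plus_one": False,
    "fdr_max": 0.05, "top_k": 20, "ease": False,
    "outdir": "netpharm_out", "seed": 0,
}

_RANGES = {
    "ob_min": (0.0, float("inf")), "dl_min": (0.0, float("inf")),
    "p_max": (0.0, 1.0), "lfc_min": (0.0, float("inf")),
    "stage1_multiplier": (0.0, float("inf")),
    "fdr_max": (0.0, 1.0), "top_k": (1, float("inf")),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; see ``validate_config``."""

    catalog: str | None = None
    targets: str | None = None
    expression: str | None = None
    groups: str | None = None
    ppi_background: str | None = None
    gene_sets_go: str | None = None
    gene_sets_kegg: str | None = None
    ob_min: float = 30.0
    dl_min: float = 0.18
    p_max: float = 0.05
    lfc_min: float = 0.5
    adjust: bool = False
    stage1_multiplier: float = 2.0
    stage1_strict: bool = False
    ecc_plus_one: bool = False
    fdr_max: float = 0.05
    top_k: int = 20
    ease: bool = False
    outdir: str = "netpharm_out"
    seed: int = 0


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Normalize a raw config mapping: inject defaults, reject unknown keys.

    All violations are collected and reported together in one
    :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors = []
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        errors.append(f"unknown config keys: {', '.join(sorted(unknown))}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            errors.append(f"{key}: expected a number, got {v!r}")
        elif not (lo <= v <= hi) or (key in ("p_max", "fdr_max") and v == 0):
            errors.append(f"{key}: value {v} out of range")
    for key in ("adjust", "stage1_strict", "ecc_plus_one", "ease"):
        if not isinstance(merged[key], bool):
            errors.append(f"{key}: expected a boolean, got {merged[key]!r}")
    if not isinstance(merged["seed"], int) or isinstance(merged["seed"], bool):
        errors.append(f"seed: expected an integer, got {merged['seed']!r}")
    if errors:
        raise ConfigError(errors)
    merged["top_k"] = int(merged["top_k"])
    return RunConfig(**merged)


@dataclass
class RunReport:
    """Machine-readable summary of every stage's headline quantities."""

    n_compounds_raw: int = 0
    n_compounds_active: int = 0
    adme_excluded: list[str] = field(default_factory=list)
    compounds_per_herb_raw: dict[str, int] = field(default_factory=dict)
    compounds_per_herb_active: dict[str, int] = field(default_factory=dict)
    targets_per_herb: dict[str, int] = field(default_factory=dict)
    n_targets_global: int = 0
    deg_counts: dict[str, int] = field(default_factory=dict)
    n_common_targets: int = 0
    compounds_with_common_target_per_herb: dict[str, int] = field(default_factory=dict)
    ct_nodes: int = 0
    ct_edges: int = 0
    ppi_nodes: int = 0
    ppi_edges: int = 0
    stage1_threshold: float = 0.0
    stage1_nodes: int = 0
    stage1_edges: int = 0
    stage2_medians: dict[str, float] = field(default_factory=dict)
    n_core_genes: int = 0
    core_genes: list[str] = field(default_factory=list)
    top_go_terms: list[dict] = field(default_factory=list)
    top_kegg_terms: list[dict] = field(default_factory=list)
    gp_nodes: int = 0
    gp_edges: int = 0
    gp_gene_count: int = 0
    gp_pathway_count: int = 0
    core_gene: str | None = None
    core_gene_tied: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def check_consistency(self) -> None:
        deg = self.deg_counts
        if deg and deg["n_up"] + deg["n_down"] + deg["n_ns"] != deg.get("n_genes", 0):
            raise NetpharmError("DEG counts do not sum to the gene count")
        for name, value in asdict(self).items():
            if isinstance(value, int) and value < 0:
                raise NetpharmError(f"negative count in report field {name}")
        if self.gp_nodes != self.gp_gene_count + self.gp_pathway_count:
            raise NetpharmError("gene-pathway node count inconsistent")

    def to_json(self, path: str | Path) -> None:
        self.check_consistency()
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _require(cfg: RunConfig, *names: str) -> None:
    missing = [n for n in names if getattr(cfg, n) is None]
    if missing:
        raise ConfigError([f"missing required input path: {n}" for n in missing])
    absent = [getattr(cfg, n) for n in names if not Path(getattr(cfg, n)).exists()]
    if absent:
        raise ConfigError([f"input file not found: {p}" for p in absent])


def run_all(cfg: RunConfig) -> RunReport:
    """Run every pipeline stage and write all artifacts under ``cfg.outdir``."""
    _require(cfg, "catalog", "targets", "expression", "groups",
             "ppi_background", "gene_sets_go", "gene_sets_kegg")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    stage = "compound screening"
    try:
        # 1. compound catalog + ADME screen
        records = compounds.read_compound_table(cfg.catalog)
        thresholds = compounds.AdmeThresholds(cfg.ob_min, cfg.dl_min)
        active = compounds.filter_adme(records, thresholds)
        report.n_compounds_raw = len(records)
        report.n_compounds_active = len(active)
        report.compounds_per_herb_raw = compounds.count_by_herb(records)
        report.compounds_per_herb_active = compounds.count_by_herb(active)
        report.adme_excluded = [f"{r.mol_id} {r.name} (ob={r.ob}, dl={r.dl})"
                                for r in records if r not in active]
        if report.adme_excluded:
            report.warnings.append(
                f"{len(report.adme_excluded)} catalog row(s) fail the ADME cutoffs "
                f"and were excluded: raw {len(records)} vs active {len(active)}")
        log.info("%s: %d raw -> %d active", stage, len(records), len(active))

        # 2. target mapping
        stage = "target mapping"
        tm = targets.read_target_table(cfg.targets)
        active_ids = {r.mol_id for r in active} & tm.mol_ids
        drug_targets = targets.distinct_targets(tm, active_ids)
        report.n_targets_global = len(drug_targets)
        herb_compounds: dict[str, set[str]] = {}
        for rec in active:
            if rec.mol_id in active_ids:
                herb_compounds.setdefault(rec.herb, set()).add(rec.mol_id)
        report.targets_per_herb = {
            herb: len(targets.distinct_targets(tm, mols))
            for herb, mols in sorted(herb_compounds.items())}
        log.info("%s: %d distinct targets", stage, len(drug_targets))

        # 3. differential expression
        stage = "differential expression"
        matrix = diffexpr.read_expression(cfg.expression, cfg.groups)
        deg_t = diffexpr.DegThresholds(cfg.p_max, cfg.lfc_min, cfg.adjust)
        deg = diffexpr.compute_deg(matrix, deg_t)
        summary = diffexpr.volcano_summary(deg)
        report.deg_counts = {**summary, "n_genes": len(deg)}
        deg.to_csv(outdir / "deg.tsv", sep="\t")
        diffexpr.volcano_plot(deg, deg_t, outdir / "volcano.png")
        disease_genes = set(deg.index[deg["status"] != "ns"])
        log.info("%s: %d up, %d down of %d genes", stage,
                 summary["n_up"], summary["n_down"], len(deg))

        # 4. common targets + compound-target network
        stage = "compound-target network"
        cts = targets.intersect_with_disease(drug_targets, disease_genes, tm)
        report.n_common_targets = len(cts.genes)
        attribution = targets.attribute_compounds(cts, tm)
        report.compounds_with_common_target_per_herb = {
            herb: len(mols) for herb, mols in sorted(attribution.items())}
        with (outdir / "common_targets.tsv").open("w") as fh:
            fh.write("gene\tn_compounds\tcompounds\n")
            for gene in sorted(cts.genes):
                mols = sorted(cts.provenance.get(gene, set()))
                fh.write(f"{gene}\t{len(mols)}\t{';'.join(mols)}\n")
        ct_net = bipartite.build_compound_target(cts, tm)
        report.ct_nodes, report.ct_edges = ct_net.n_nodes, ct_net.n_edges
        bipartite.export_bipartite(ct_net, outdir / "compound_target.graphml")
        log.info("%s: %d nodes, %d edges", stage, ct_net.n_nodes, ct_net.n_edges)

        # 5. PPI network + two-stage hub screen
        stage = "PPI screening"
        background = []
        with open(cfg.ppi_background) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0].strip():
                    background.append((parts[0].strip(), parts[1].strip()))
        net = ppi.build_seeded_network(cts.genes, background)
        report.ppi_nodes, report.ppi_edges = net.n_nodes, net.n_edges
        if net.n_nodes == 0:
            report.warnings.append("no common target present in the PPI background")
            screen = ppi.ScreenResult(0.0, set(), set(), {})
        else:
            screen = ppi.two_stage_screen(net, cfg.stage1_multiplier,
                                          cfg.stage1_strict, cfg.ecc_plus_one)
        report.stage1_threshold = screen.stage1_threshold
        report.stage1_nodes = len(screen.stage1_nodes)
        g1 = net.subgraph(screen.stage1_nodes)
        report.stage1_edges = g1.n_edges
        report.stage2_medians = screen.stage2_medians
        report.n_core_genes = len(screen.core_nodes)
        report.core_genes = sorted(screen.core_nodes)
        ppi.write_network(net, outdir / "ppi_network.sif")
        ppi.write_network(net.subgraph(screen.core_nodes), outdir / "ppi_core.sif")
        if screen.stage2_table is not None:
            screen.stage2_table.to_csv(outdir / "centralities_stage2.tsv", sep="\t")
        with (outdir / "screen_result.json").open("w") as fh:
            json.dump(screen.to_dict(), fh, indent=1)
        log.info("%s: %d -> %d -> %d nodes", stage, net.n_nodes,
                 len(screen.stage1_nodes), len(screen.core_nodes))

        # 6. GO and KEGG over-representation
        stage = "enrichment"
        go_rows = enrichment.enrich(cts.genes, enrichment.read_gmt(cfg.gene_sets_go),
                                    cfg.fdr_max, cfg.top_k, cfg.ease)
        kegg_rows = enrichment.enrich(cts.genes, enrichment.read_gmt(cfg.gene_sets_kegg),
                                      cfg.fdr_max, cfg.top_k, cfg.ease)
        for name, rows in (("go", go_rows), ("kegg", kegg_rows)):
            with (outdir / f"enrichment_{name}.tsv").open("w") as fh:
                fh.write("term_id\tname\tcategory\tk\tK\tn\tN\tp\tfdr\t"
                         "gene_ratio\tmembers\n")
                for r in rows:
                    fh.write(f"{r.term_id}\t{r.name}\t{r.category}\t{r.k}\t{r.K}\t"
                             f"{r.n}\t{r.N}\t{r.p:.6g}\t{r.fdr:.6g}\t"
                             f"{r.gene_ratio:.6g}\t{';'.join(sorted(r.members))}\n")
        summarize = lambda r: {"term_id": r.term_id, "name": r.name, "k": r.k,
                               "fdr": r.fdr, "gene_ratio": r.gene_ratio}
        report.top_go_terms = [summarize(r) for r in go_rows]
        report.top_kegg_terms = [summarize(r) for r in kegg_rows]
        if kegg_rows:
            enrichment.dotplot(kegg_rows, outdir / "kegg_dotplot.png")
        log.info("%s: %d GO terms, %d KEGG pathways retained", stage,
                 len(go_rows), len(kegg_rows))

        # 7. gene-pathway network, core gene
        stage = "gene-pathway network"
        gp = bipartite.build_gene_pathway(kegg_rows)
        report.gp_nodes, report.gp_edges = gp.n_nodes, gp.n_edges
        report.gp_gene_count = len(gp.left_nodes)
        report.gp_pathway_count = len(gp.right_nodes)
        ranking = bipartite.rank_by_degree(gp, side="left")
        if ranking:
            report.core_gene = ranking[0][0]
            top_degree = ranking[0][1]
            tied = [g for g, d in ranking if d == top_degree]
            if len(tied) > 1:
                report.core_gene_tied = tied
                report.warnings.append(
                    f"core-gene degree tie among {len(tied)} genes; "
                    "lexicographically first reported")
        with (outdir / "gene_pathway_ranking.tsv").open("w") as fh:
            fh.write("gene\tdegree\n")
            for gene, degree in ranking:
                fh.write(f"{gene}\t{degree}\n")
        bipartite.export_bipartite(gp, outdir / "gene_pathway.graphml")
        log.info("%s: %d genes x %d pathways, core gene %s", stage,
                 report.gp_gene_count, report.gp_pathway_count, report.core_gene)
    except NetpharmError as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise NetpharmError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report.to_json(outdir / "run_report.json")
    return report
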