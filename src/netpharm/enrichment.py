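"""Over-representation analysis against GO/KEGG-style gene-set collections.

Each term is scored with the hypergeometric upper tail
P(X >= k), X ~ Hypergeometric(N, K, n): drawing the n input genes from a
background of N annotated genes of which K belong to the term, and observing
an overlap of k. Tail sums are accumulated in log space for numerical
stability. An optional EASE variant (the conservative DAVID score) replaces
k with k - 1. P-values are adjusted with Benjamini-Hochberg across all
tested terms; terms with FDR below the cutoff are ranked by
(fdr, p, term_id) and truncated to the top k. GeneRatio is k / n, the
fraction of the (background-restricted) input list falling in the term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, NetpharmError
from .targets import canonical_symbol

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "hypergeom_upper",
    "bh_adjust",
    "enrich",
    "dotplot",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with category labels over a common background.

    ``terms`` maps term-id -> (name, category, member genes). The background
    defaults to the union of all members; a wider user-supplied universe is
    allowed, but members outside it are an error.
    """

    terms: dict[str, tuple[str, str, set[str]]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for tid, (_, _, members) in self.terms.items():
            if not members:
                raise FormatError(f"term {tid!r} has no member genes")
            union |= members
        if not self.background:
            self.background = union
        elif not union <= self.background:
            missing = sorted(union - self.background)[:5]
            raise FormatError(f"member genes outside background, e.g. {missing}")


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result."""

    term_id: str
    name: str
    category: str
    k: int        # overlap size
    K: int        # term size within background
    n: int        # input-list size within background
    N: int        # background size
    p: float
    fdr: float
    gene_ratio: float
    members: frozenset[str]


def read_gmt(source: str | Path | IO[str],
             category: str = "") -> GeneSetCollection:
    """Read a GMT file (term_id<TAB>description<TAB>gene...).

    The description field may encode the category as ``category|name``;
    otherwise ``category`` applies to every term.
    """
    close = False
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source)
        close = True
    else:
        fh = source
    terms: dict[str, tuple[str, str, set[str]]] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT rows need id, description "
                                  f"and >=1 gene")
            tid, desc = parts[0], parts[1]
            cat, name = (desc.split("|", 1) if "|" in desc else (category, desc))
            genes = {canonical_symbol(g) for g in parts[2:] if g.strip()}
            if not genes:
                raise FormatError(f"line {lineno}: term {tid!r} has no genes")
            terms[tid] = (name, cat, genes)
    finally:
        if close:
            fh.close()
    return GeneSetCollection(terms=terms)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for tid in sorted(coll.terms):
            name, cat, members = coll.terms[tid]
            desc = f"{cat}|{name}" if cat else name
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), via log-space sum."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise NetpharmError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise NetpharmError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(genes: Iterable[str],
           coll: GeneSetCollection,
           fdr_max: float = 0.05,
           top_k: int | None = 20,
           ease: bool = False) -> list[EnrichmentRow]:
    """Rank a gene list's over-represented terms.

    Input genes outside the collection background are dropped (their count is
    available as the difference from ``len(genes)``). Every term with overlap
    k >= 1 is tested; BH-FDR is computed across those tests; rows with
    fdr < fdr_max are sorted by (fdr, p, term_id) and truncated to ``top_k``
    (None = no truncation). ``ease`` switches to the conservative k - 1 tail.
    """
    if not 0 < fdr_max <= 1:
        raise NetpharmError(f"fdr_max must be in (0, 1], got {fdr_max}")
    if top_k is not None and top_k < 1:
        raise NetpharmError(f"top_k must be >= 1, got {top_k}")
    query = {canonical_symbol(g) for g in genes} & coll.background
    N = len(coll.background)
    n = len(query)
    if n == 0:
        return []
    tested: list[tuple[str, int, int, frozenset[str]]] = []
    for tid in sorted(coll.terms):
        _, _, members = coll.terms[tid]
        overlap = query & members
        if overlap:
            tested.append((tid, len(overlap), len(members), frozenset(overlap)))
    if not tested:
        return []
    pvals = []
    for tid, k, K, _ in tested:
        k_eff = max(k - 1, 0) if ease else k
        pvals.append(hypergeom_upper(k_eff, K, n, N))
    fdrs = bh_adjust(pvals)
    rows = []
    for (tid, k, K, overlap), p, fdr in zip(tested, pvals, fdrs):
        name, cat, _ = coll.terms[tid]
        rows.append(EnrichmentRow(term_id=tid, name=name, category=cat,
                                  k=k, K=K, n=n, N=N,
                                  p=float(p), fdr=float(fdr),
                                  gene_ratio=k / n, members=overlap))
    rows = [r for r in rows if r.fdr < fdr_max]
    rows.sort(key=lambda r: (r.fdr, r.p, r.term_id))
    return rows if top_k is None else rows[:top_k]


def dotplot(rows: Sequence[EnrichmentRow], out: str | Path | None = None):
    """Enrichment dot plot: GeneRatio on x, terms on y, size k, color FDR."""
    if not rows:
        raise NetpharmError("dotplot requires at least one enrichment row")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(rows, key=lambda r: (r.fdr, r.p, r.term_id), reverse=True)
    ratios = [r.gene_ratio for r in rows]
    names = [r.name or r.term_id for r in rows]
    ks = [r.k for r in rows]
    fdrs = [r.fdr for r in rows]
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(rows) + 1)))
    sc = ax.scatter(ratios, range(len(rows)),
                    s=[30 + 12 * k for k in ks], c=fdrs, cmap="RdBu")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(names, fontsize=7)
    ax.set_xlabel("GeneRatio")
    fig.colorbar(sc, ax=ax, label="FDR")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
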