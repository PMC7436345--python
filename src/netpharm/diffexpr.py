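"""Two-group differential expression on log2-scale expression matrices.

The disease signature is computed gene-by-gene between case and control
samples: the effect size is the difference of group means on the log2 scale
(i.e. a log2 fold change), significance comes from a two-sided Welch t-test
(unequal variances, Welch-Satterthwaite degrees of freedom), and
Benjamini-Hochberg adjusted p-values are always computed alongside. A gene
is called *up* when log2fc > lfc_min and p* < p_max, *down* when
log2fc < -lfc_min and p* < p_max, and *ns* otherwise, where p* is the raw p
by default and the BH-adjusted p when ``adjust`` is enabled. Defaults
(p < 0.05, |log2fc| > 0.5) follow common microarray volcano practice.

Welch's t-test is used deliberately: it is exactly specified, assumption-
light on log-intensity data, and easy to cross-check against closed forms.
A moderated-variance model can be substituted upstream if desired — the
thresholding logic only needs per-gene (log2fc, p) pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "ExpressionMatrix",
    "DegThresholds",
    "compute_deg",
    "volcano_summary",
    "volcano_plot",
    "read_expression",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity matrix with a two-group design."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray          # shape (n_genes, n_samples)
    group_of: Mapping[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise IntegrityError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples")
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError("duplicate gene symbols in expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("expression matrix contains non-finite values")
        bad = [s for s in self.samples if self.group_of.get(s) not in ("case", "control")]
        if bad:
            raise IntegrityError(f"samples without case/control label: {bad}")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.group_of[s] == group]
        return self.values[:, idx]


@dataclass(frozen=True)
class DegThresholds:
    """Volcano cutoffs: significance level, absolute log2fc, BH switch."""

    p_max: float = 0.05
    lfc_min: float = 0.5
    adjust: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_max <= 1:
            raise ConfigError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.lfc_min < 0:
            raise ConfigError(f"lfc_min must be >= 0, got {self.lfc_min}")


def _welch(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch p-values per row; degenerate rows handled.

    A row where both groups have zero variance gets p = 1 when the means are
    equal (no evidence of change) and p = 0 when they differ (the difference
    is exact, noiseless).
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; they are
        # resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    if np.any(zero_var):
        equal = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
        p = np.where(zero_var & equal, 1.0, p)
        p = np.where(zero_var & ~equal, 0.0, p)
    return np.asarray(p, dtype=float)


def compute_deg(m: ExpressionMatrix,
                t: DegThresholds = DegThresholds(),
                log2_transform: bool = False) -> pd.DataFrame:
    """Per-gene differential-expression table.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (case mean
    minus control mean), ``p`` (two-sided Welch), ``p_adj`` (BH over all
    genes) and ``status`` in {up, down, ns}. Set ``log2_transform`` for
    linear-scale input.
    """
    case = m.group_columns("case")
    ctrl = m.group_columns("control")
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ConfigError("each group needs at least 2 samples for the Welch test")
    if log2_transform:
        case = np.log2(case)
        ctrl = np.log2(ctrl)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    p = _welch(case, ctrl)
    p_adj = multipletests(p, method="fdr_bh")[1]
    p_eff = p_adj if t.adjust else p
    status = np.full(len(m.genes), "ns", dtype=object)
    status[(log2fc > t.lfc_min) & (p_eff < t.p_max)] = "up"
    status[(log2fc < -t.lfc_min) & (p_eff < t.p_max)] = "down"
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj, "status": status},
        index=pd.Index(m.genes, name="gene"),
    )


def volcano_summary(deg: pd.DataFrame) -> dict[str, int]:
    """Counts of up/down/ns calls; they always sum to the number of genes."""
    counts = deg["status"].value_counts()
    return {"n_up": int(counts.get("up", 0)),
            "n_down": int(counts.get("down", 0)),
            "n_ns": int(counts.get("ns", 0))}


def volcano_plot(deg: pd.DataFrame,
                 t: DegThresholds = DegThresholds(),
                 out: str | Path | None = None):
    """Volcano scatter: log2fc vs -log10 p, up red / down green / ns grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"up": "#d62728", "down": "#2ca02c", "ns": "#b0b0b0"}
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(deg["p"].to_numpy(dtype=float)) if len(deg) else np.array([])
    for status, color in colors.items():
        mask = (deg["status"] == status).to_numpy() if len(deg) else np.array([], bool)
        ax.scatter(deg["log2fc"].to_numpy()[mask] if len(deg) else [],
                   neglogp[mask] if len(deg) else [],
                   s=6, c=color, label=status, linewidths=0)
    ax.axhline(-np.log10(t.p_max), ls="--", lw=0.6, c="k")
    for x in (t.lfc_min, -t.lfc_min):
        ax.axvline(x, ls="--", lw=0.6, c="k")
    ax.set_xlabel("log2 fold change (case - control)")
    ax.set_ylabel("-log10 P value")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def read_expression(matrix_source: str | Path | IO[str],
                    groups_source: str | Path | IO[str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene) and a sample-group TSV.

    The group file has two columns, sample and group, where group is
    ``case`` or ``control``; a header row is optional.
    """
    df = pd.read_csv(matrix_source, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicate gene symbols in expression matrix")
    group_of: dict[str, str] = {}
    close = False
    if isinstance(groups_source, (str, Path)):
        fh: IO[str] = open(groups_source, newline="")
        close = True
    else:
        fh = groups_source
    try:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or all(not c.strip() for c in row):
                continue
            sample, group = row[0].strip(), row[1].strip().lower()
            if group in ("case", "control"):
                group_of[sample] = group
            elif sample.lower() in ("sample", "id"):
                continue  # header
            else:
                raise FormatError(f"unknown group label {group!r} for sample {sample!r}")
    finally:
        if close:
            fh.close()
    missing = [s for s in df.columns if s not in group_of]
    if missing:
        raise FormatError(f"samples without group assignment: {missing}")
    return ExpressionMatrix(genes=[str(g) for g in df.index],
                            samples=[str(s) for s in df.columns],
                            values=df.to_numpy(dtype=float),
                            group_of=group_of)
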