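"""Compound-target mappings and the drug/disease common-target intersection.

The drug side of the pipeline resolves each active compound to the set of
genes (targets) it is known to act on; the disease side contributes the
differentially expressed genes. Their intersection — the *common targets* —
seeds every downstream network stage. Gene symbols are treated as opaque
canonical tokens: trimmed and uppercased, with no alias resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from .errors import FormatError, LookupError_, RowError

__all__ = [
    "canonical_symbol",
    "TargetMap",
    "CommonTargetSet",
    "read_target_table",
    "distinct_targets",
    "intersect_with_disease",
    "attribute_compounds",
]


def canonical_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and uppercased."""
    return symbol.strip().upper()


@dataclass
class TargetMap:
    """Bipartite compound -> gene-symbol mapping with herb provenance.

    ``edges`` holds deduplicated (mol_id, gene_symbol) pairs; ``herb_of``
    maps each compound to the set of herbs it was catalogued under.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    herb_of: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mol, gene in self.edges:
            if not gene:
                raise FormatError("empty gene symbol in target map")
            if mol not in self.herb_of:
                # tolerate maps built without herb annotation
                self.herb_of[mol] = set()

    @property
    def mol_ids(self) -> set[str]:
        return {mol for mol, _ in self.edges} | set(self.herb_of)

    @property
    def genes(self) -> set[str]:
        return {gene for _, gene in self.edges}

    def targets_of(self, mol_id: str) -> set[str]:
        return {g for m, g in self.edges if m == mol_id}


@dataclass
class CommonTargetSet:
    """Intersection of drug targets with disease genes, with provenance.

    ``provenance`` maps each common gene to the compounds that hit it; it is
    empty only when no TargetMap was supplied at construction.
    """

    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, mols in self.provenance.items():
            if gene in self.genes and not mols:
                raise FormatError(f"common target {gene} has empty provenance")


def read_target_table(source: str | Path | IO[str],
                      delimiter: str | None = None) -> TargetMap:
    """Read a compound-target edge table (columns mol_id, gene_symbol[, herb]).

    Pairs are deduplicated after canonicalizing symbols; mol ids are kept
    verbatim apart from whitespace trimming.
    """
    close = False
    if isinstance(source, (str, Path)):
        path = Path(source)
        if delimiter is None:
            delimiter = "," if path.suffix.lower() == ".csv" else "\t"
        fh: IO[str] = path.open(newline="")
        close = True
    else:
        fh = source
        if delimiter is None:
            delimiter = "\t"
    try:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise FormatError("empty input: no header row") from None
        try:
            i_mol = header.index("mol_id")
            i_gene = header.index("gene_symbol")
        except ValueError as exc:
            raise FormatError(f"missing required column ({exc})") from None
        i_herb = header.index("herb") if "herb" in header else None

        tm = TargetMap()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            mol = row[i_mol].strip()
            gene = canonical_symbol(row[i_gene])
            if not gene:
                raise RowError(rownum, "empty gene symbol")
            if not mol:
                raise RowError(rownum, "empty mol_id")
            tm.edges.add((mol, gene))
            herbs = tm.herb_of.setdefault(mol, set())
            if i_herb is not None and row[i_herb].strip():
                herbs.add(row[i_herb].strip())
        return tm
    finally:
        if close:
            fh.close()


def distinct_targets(tm: TargetMap, compounds: Iterable[str]) -> set[str]:
    """Union of the target sets of the given compounds (duplicates discarded)."""
    compounds = set(compounds)
    unknown = compounds - tm.mol_ids
    if unknown:
        raise LookupError_(f"unknown mol_id(s): {', '.join(sorted(unknown))}")
    return {g for m, g in tm.edges if m in compounds}


def intersect_with_disease(drug_targets: set[str],
                           disease_genes: set[str],
                           tm: TargetMap | None = None) -> CommonTargetSet:
    """Intersect drug targets with disease genes; attach compound provenance.

    Both inputs are expected in canonical symbol form. When ``tm`` is given,
    each common gene is annotated with the compounds mapping to it.
    """
    common = set(drug_targets) & set(disease_genes)
    provenance: dict[str, set[str]] = {}
    if tm is not None:
        for mol, gene in tm.edges:
            if gene in common:
                provenance.setdefault(gene, set()).add(mol)
    return CommonTargetSet(genes=common, provenance=provenance)


def attribute_compounds(cts: CommonTargetSet,
                        tm: TargetMap) -> dict[str, set[str]]:
    """Group the compounds hitting >=1 common target by source herb.

    A compound catalogued under several herbs appears in each herb's group
    and additionally under the key ``"shared"``.
    """
    hitting = {mol for mol, gene in tm.edges if gene in cts.genes}
    groups: dict[str, set[str]] = {}
    for mol in hitting:
        herbs = tm.herb_of.get(mol, set())
        for herb in herbs:
            groups.setdefault(herb, set()).add(mol)
        if len(herbs) > 1:
            groups.setdefault("shared", set()).add(mol)
    return groups
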