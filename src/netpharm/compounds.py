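"""Herb-ingredient catalogs and ADME (OB/DL) activity screening.

A compound catalog lists herbal ingredients with two pharmacokinetic scores:
oral bioavailability (OB, percent) and drug-likeness (DL, in [0, 1]).
Screening keeps compounds with OB >= 30% and DL >= 0.18 by default, the
standard TCMSP activity thresholds. Both comparisons are inclusive.

The packaged catalog ``table1_sxd.tsv`` transcribes the published ingredient
table of Sanhuang Xiexin decoction (SXD): 67 rows across the three herbs
Dahuang, Huanglian and Huangqin. One transcribed row (Baicalin, OB 29.53)
sits below the OB cutoff, so strict filtering retains 66 of the 67 rows; the
pipeline run report surfaces both counts rather than patching the table.
"""

from __future__ import annotations

import csv
import importlib.resources
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .errors import FormatError, IntegrityError, RowError

__all__ = [
    "CompoundRecord",
    "AdmeThresholds",
    "read_compound_table",
    "load_packaged_catalog",
    "filter_adme",
    "count_by_herb",
]

# accepted header aliases, all matched case-insensitively
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "mol_id": ("mol_id", "id", "molecule_id", "mol id"),
    "name": ("name", "compound", "compound_name"),
    "ob": ("ob", "ob%", "oral_bioavailability"),
    "dl": ("dl", "drug_likeness", "druglikeness"),
    "herb": ("herb", "source", "source_herb"),
}


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its ADME screening scores."""

    mol_id: str
    name: str
    ob: float   # oral bioavailability, percent
    dl: float   # drug-likeness index, dimensionless
    herb: str

    def __post_init__(self) -> None:
        if not self.mol_id or not self.name:
            raise IntegrityError("mol_id and name must be non-empty")
        if self.ob < 0:
            raise IntegrityError(f"{self.mol_id}: ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise IntegrityError(f"{self.mol_id}: dl must be in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class AdmeThresholds:
    """Inclusive lower cutoffs for the OB/DL activity screen."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if self.ob_min < 0 or self.dl_min < 0:
            raise IntegrityError("ADME thresholds must be non-negative")


def _resolve_columns(header: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, int]:
    """Map canonical field names to column indices, case-insensitively."""
    lowered = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    for field, aliases in _COLUMN_ALIASES.items():
        wanted = (column_map.get(field, "").lower(),) if column_map and field in column_map \
            else aliases
        for alias in wanted:
            if alias in lowered:
                out[field] = lowered.index(alias)
                break
        else:
            raise FormatError(f"missing required column: {field!r} "
                              f"(accepted names: {', '.join(aliases)})")
    return out


def read_compound_table(source: str | Path | IO[str],
                        delimiter: str | None = None,
                        column_map: Mapping[str, str] | None = None,
                        ) -> list[CompoundRecord]:
    """Read a compound catalog from a delimited text table.

    ``delimiter`` defaults to tab for ``.tsv`` paths and comma for ``.csv``;
    streams default to tab. ``column_map`` optionally renames the expected
    columns (canonical name -> actual header).

    Raises :class:`FormatError` for a missing column, :class:`RowError` for a
    non-numeric OB/DL value, and :class:`IntegrityError` for a duplicate
    (mol_id, herb) pair.
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
            header = next(reader)
        except StopIteration:
            raise FormatError("empty input: no header row") from None
        cols = _resolve_columns(header, column_map)
        records: list[CompoundRecord] = []
        seen: set[tuple[str, str]] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                ob = float(row[cols["ob"]])
                dl = float(row[cols["dl"]])
            except (ValueError, IndexError) as exc:
                raise RowError(rownum, f"non-numeric ob/dl value ({exc})") from None
            rec = CompoundRecord(
                mol_id=row[cols["mol_id"]].strip(),
                name=row[cols["name"]].strip(),
                ob=ob, dl=dl,
                herb=row[cols["herb"]].strip(),
            )
            key = (rec.mol_id, rec.herb)
            if key in seen:
                raise IntegrityError(f"duplicate (mol_id, herb) pair: {key}")
            seen.add(key)
            records.append(rec)
        return records
    finally:
        if close:
            fh.close()


def load_packaged_catalog() -> list[CompoundRecord]:
    """Load the packaged 67-row SXD ingredient catalog."""
    ref = importlib.resources.files("netpharm.data") / "table1_sxd.tsv"
    with ref.open() as fh:
        return read_compound_table(fh, delimiter="\t")


def filter_adme(records: Iterable[CompoundRecord],
                thresholds: AdmeThresholds = AdmeThresholds(),
                ) -> list[CompoundRecord]:
    """Keep records with ob >= ob_min and dl >= dl_min, preserving order."""
    return [r for r in records
            if r.ob >= thresholds.ob_min and r.dl >= thresholds.dl_min]


def count_by_herb(records: Iterable[CompoundRecord]) -> dict[str, int]:
    """Count records per source herb."""
    return dict(Counter(r.herb for r in records))
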