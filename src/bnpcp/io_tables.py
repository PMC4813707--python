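"""Reading, writing, validation and QC filtering of per-fraction quantitation tables.

This module owns every file dialect consumed by the pipeline:

* quantitation tables: tab-delimited text with one ``Intensity <k>`` and one
  ``iBAQ <k>`` column per gel fraction, plus ``+``-convention marker columns
  for contaminant / reverse / only-identified-by-site flags (the common
  proteomics search-engine export dialect);
* control lists: one protein identifier per line (nonspecific binders drawn
  from control purifications);
* marker ladders: two-column TSV mapping fraction index to kDa.

Fraction indices are 1-based throughout; fraction 1 is the gel bottom
(lowest apparent mass).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LadderError, TableFormatError

__all__ = [
    "QuantTable",
    "ControlList",
    "read_quant_table",
    "write_quant_table",
    "filter_quant_table",
    "read_control_list",
    "read_marker_ladder",
    "write_marker_ladder",
]

#: Column headers used by the table dialect.
ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
FLAG_COLUMNS = {
    "flag_contaminant": "Potential contaminant",
    "flag_reverse": "Reverse",
    "flag_only_by_site": "Only identified by site",
}


@dataclass
class QuantTable:
    """Per-protein, per-fraction intensity and iBAQ matrix with QC flags.

    All per-fraction arrays are shaped ``(n_proteins, n_fractions)``; fraction
    axis order follows ``fraction_labels`` (ascending numeric fraction index).
    """

    protein_ids: list[str]
    gene_names: list[str]
    intensity: np.ndarray
    ibaq: np.ndarray
    flag_contaminant: np.ndarray
    flag_reverse: np.ndarray
    flag_only_by_site: np.ndarray
    fraction_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.ibaq = np.asarray(self.ibaq, dtype=float)
        for name in ("flag_contaminant", "flag_reverse", "flag_only_by_site"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not self.fraction_labels:
            self.fraction_labels = [str(k + 1) for k in range(self.intensity.shape[1])]
        self.validate()

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_fractions(self) -> int:
        return self.intensity.shape[1]

    def validate(self) -> None:
        n = self.n_proteins
        if len(self.gene_names) != n:
            raise TableFormatError("gene_names length does not match protein_ids")
        if len(set(self.protein_ids)) != n:
            raise TableFormatError("duplicate protein_id in table")
        for name in ("intensity", "ibaq"):
            mat = getattr(self, name)
            if mat.shape != (n, len(self.fraction_labels)):
                raise TableFormatError(f"{name} matrix shape {mat.shape} inconsistent")
            if np.any(mat < 0):
                raise TableFormatError(f"negative value in {name} matrix")
        for name in ("flag_contaminant", "flag_reverse", "flag_only_by_site"):
            if getattr(self, name).shape != (n,):
                raise TableFormatError(f"{name} vector length inconsistent")

    def index_of(self, protein_id: str) -> int:
        """Row index of *protein_id*; raises ``KeyError`` if absent."""
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein_id {protein_id!r} not in table") from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.protein_ids

    def subset(self, keep: Sequence[int]) -> "QuantTable":
        """New table containing only the rows in *keep*, order preserved."""
        keep = list(keep)
        return QuantTable(
            protein_ids=[self.protein_ids[i] for i in keep],
            gene_names=[self.gene_names[i] for i in keep],
            intensity=self.intensity[keep].copy(),
            ibaq=self.ibaq[keep].copy(),
            flag_contaminant=self.flag_contaminant[keep].copy(),
            flag_reverse=self.flag_reverse[keep].copy(),
            flag_only_by_site=self.flag_only_by_site[keep].copy(),
            fraction_labels=list(self.fraction_labels),
        )


@dataclass(frozen=True)
class ControlList:
    """Identifiers of nonspecific binders observed in control purifications."""

    protein_ids: frozenset[str] = frozenset()

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "ControlList":
        return cls(frozenset(str(i).strip() for i in ids if str(i).strip()))

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.protein_ids

    def __len__(self) -> int:
        return len(self.protein_ids)


def _canonical_id(raw: str) -> str:
    # First entry of a semicolon-separated protein group is the majority protein.
    return str(raw).split(";")[0].strip()


def _fraction_columns(columns: Sequence[str], prefix: str) -> list[tuple[int, str]]:
    """(numeric suffix, column name) pairs for columns ``<prefix> <k>``, sorted by k."""
    pat = re.compile(rf"^{re.escape(prefix)}\s+(\d+)$")
    found = []
    for col in columns:
        m = pat.match(col)
        if m:
            found.append((int(m.group(1)), col))
    found.sort(key=lambda t: t[0])
    return found


def read_quant_table(path: str | Path, fraction_column_pattern: str = "Intensity") -> QuantTable:
    """Read a tab-delimited quantitation table.

    Parameters
    ----------
    path:
        TSV file in the dialect described in the module docstring.
    fraction_column_pattern:
        Prefix of the intensity fraction columns (default ``"Intensity"``).
        iBAQ columns are expected under the ``"iBAQ"`` prefix with matching
        numeric suffixes; if absent, iBAQ defaults to the intensity values.

    Fraction columns are ordered by their numeric suffix regardless of file
    order; blank cells are read as 0 (never imputed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if ID_COLUMN not in df.columns:
        raise TableFormatError(f"missing required column {ID_COLUMN!r} in {path}")

    int_cols = _fraction_columns(df.columns, fraction_column_pattern)
    if len(int_cols) < 2:
        raise TableFormatError(
            f"found {len(int_cols)} fraction columns matching "
            f"{fraction_column_pattern!r}; need at least 2"
        )
    ibaq_cols = dict(_fraction_columns(df.columns, "iBAQ"))

    def numeric(col: pd.Series, name: str) -> np.ndarray:
        vals = pd.to_numeric(col.replace("", "0"), errors="coerce")
        if vals.isna().any():
            raise TableFormatError(f"non-numeric cell in column {name!r}")
        return vals.to_numpy(dtype=float)

    intensity = np.column_stack([numeric(df[c], c) for _, c in int_cols])
    if np.any(intensity < 0):
        raise TableFormatError("negative intensity value")
    if ibaq_cols:
        missing = [k for k, _ in int_cols if k not in ibaq_cols]
        if missing:
            raise TableFormatError(f"iBAQ columns missing for fractions {missing}")
        ibaq = np.column_stack([numeric(df[ibaq_cols[k]], ibaq_cols[k]) for k, _ in int_cols])
        if np.any(ibaq < 0):
            raise TableFormatError("negative iBAQ value")
    else:
        ibaq = intensity.copy()

    ids = [_canonical_id(v) for v in df[ID_COLUMN]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableFormatError(f"duplicate protein_id(s): {dupes}")
    genes = [str(v).strip() for v in df[GENE_COLUMN]] if GENE_COLUMN in df.columns else list(ids)

    flags = {}
    for attr, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[attr] = df[col].astype(str).str.strip().eq("+").to_numpy()
        else:
            flags[attr] = np.zeros(len(ids), dtype=bool)

    return QuantTable(
        protein_ids=ids,
        gene_names=genes,
        intensity=intensity,
        ibaq=ibaq,
        fraction_labels=[str(k) for k, _ in int_cols],
        **flags,
    )


def write_quant_table(table: QuantTable, path: str | Path) -> Path:
    """Write *table* in the same TSV dialect accepted by :func:`read_quant_table`."""
    path = Path(path)
    cols: dict[str, object] = {
        ID_COLUMN: table.protein_ids,
        GENE_COLUMN: table.gene_names,
    }
    for k, label in enumerate(table.fraction_labels):
        cols[f"Intensity {label}"] = table.intensity[:, k]
    for k, label in enumerate(table.fraction_labels):
        cols[f"iBAQ {label}"] = table.ibaq[:, k]
    for attr, col in FLAG_COLUMNS.items():
        cols[col] = np.where(getattr(table, attr), "+", "")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


def filter_quant_table(
    table: QuantTable,
    controls: ControlList | None = None,
    remove_controls: bool = True,
) -> QuantTable:
    """Drop records with any QC flag set, and optionally control-list members.

    Survivor order is preserved and vectors are untouched. With
    ``remove_controls=False`` control-list membership is ignored here
    (annotate-only mode); QC-flagged records are always removed.
    """
    controls = controls or ControlList()
    keep = [
        i
        for i in range(table.n_proteins)
        if not (
            table.flag_contaminant[i]
            or table.flag_reverse[i]
            or table.flag_only_by_site[i]
            or (remove_controls and table.protein_ids[i] in controls)
        )
    ]
    return table.subset(keep)


def read_control_list(path: str | Path) -> ControlList:
    """Read a control list: one protein id per line, ``#`` comments allowed."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ControlList.from_iterable(ids)


def read_marker_ladder(path: str | Path) -> list[tuple[int, float]]:
    """Read a 2-column (fraction, kDa) TSV ladder, sorted by fraction.

    Masses must be strictly monotone (in either direction) in fraction order.
    """
    rows: list[tuple[int, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise LadderError(f"marker ladder line lacks two columns: {line!r}")
        try:
            frac, mass = int(parts[0]), float(parts[1])
        except ValueError:
            # tolerate a single header row
            if not rows:
                continue
            raise LadderError(f"non-numeric marker ladder row: {line!r}") from None
        rows.append((frac, mass))
    return validate_ladder(rows)


def validate_ladder(rows: Sequence[tuple[int, float]]) -> list[tuple[int, float]]:
    """Sort a (fraction, kDa) ladder by fraction and enforce strict monotonicity."""
    rows = sorted((int(f), float(m)) for f, m in rows)
    if len(rows) < 2:
        raise LadderError("marker ladder needs at least 2 rows")
    if any(m <= 0 for _, m in rows):
        raise LadderError("marker masses must be positive")
    fracs = [f for f, _ in rows]
    if len(set(fracs)) != len(fracs):
        raise LadderError("duplicate fraction in marker ladder")
    masses = [m for _, m in rows]
    diffs = np.diff(masses)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise LadderError("marker masses must be strictly monotone in fraction order")
    return rows


def write_marker_ladder(rows: Sequence[tuple[int, float]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("fraction\tmass_kda\n")
        for frac, mass in rows:
            fh.write(f"{frac}\t{mass:g}\n")
    return path
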