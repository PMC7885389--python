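"""Tabular containers and I/O for the prioritization pipeline.

The pipeline moves four kinds of tables around: FPKM expression matrices,
per-sample clinical annotations (receptor status, PAM50 subtype, survival),
discrete copy-number call matrices, and cell-line drug-sensitivity panels.
All of them are thin, validated wrappers around :class:`pandas.DataFrame`
so that downstream stages can rely on a few invariants (unique identifiers,
non-negative FPKM, the five-level copy-number alphabet) without re-checking.

On disk every table is plain TSV: UTF-8, tab-separated, ``.`` decimal, no
quoting. Gene symbols are case-preserved and matched case-sensitively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ZScoreMatrix",
    "ClinicalTable",
    "CopyNumberTable",
    "CellLinePanel",
    "GeneList",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_cna",
    "write_cna",
    "read_panel",
    "write_panel",
    "read_gene_list",
    "write_gene_list",
    "log2_fpkm",
    "zscore",
    "select_tnbc",
]

RECEPTOR_STATUSES = ("positive", "negative", "unknown")
PAM50_SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal-like")
CNA_ALPHABET = (-2, -1, 0, 1, 2)

CLINICAL_COLUMNS = (
    "ER",
    "PR",
    "HER2",
    "PAM50",
    "OS_time",
    "OS_event",
    "DMFS_time",
    "DMFS_event",
)


class TableValidationError(ValueError):
    """A table violated one of its structural invariants."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise TableValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative FPKM values, genes in rows, samples in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "gene symbol")
        _check_unique(df.columns.astype(str), "sample id")
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise TableValidationError(
                f"missing FPKM value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative FPKM value {arr[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def gene_row(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene not in expression matrix: {gene!r}")
        return self.values.loc[gene]


@dataclass(frozen=True)
class ZScoreMatrix:
    """Per-gene standardized log2(FPKM+1) expression, genes x samples."""

    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_row(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene not in z-score matrix: {gene!r}")
        return self.values.loc[gene]


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample receptor status, PAM50 label and survival endpoints.

    ``OS_time``/``DMFS_time`` are in months and must be positive where
    present; event flags are 0 (censored) or 1 (event).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "sample id")
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise TableValidationError(f"clinical table missing columns: {missing_cols}")
        for col in ("ER", "PR", "HER2"):
            bad = set(df[col]) - set(RECEPTOR_STATUSES)
            if bad:
                raise TableValidationError(f"invalid {col} status values: {sorted(bad)}")
        bad = set(df["PAM50"]) - set(PAM50_SUBTYPES) - {"unknown"}
        if bad:
            raise TableValidationError(f"invalid PAM50 labels: {sorted(bad)}")
        for col in ("OS_time", "DMFS_time"):
            t = pd.to_numeric(df[col], errors="raise")
            if (t.dropna() <= 0).any():
                sample = t.index[t <= 0][0]
                raise TableValidationError(
                    f"non-positive {col} for sample {sample!r}"
                )
        for col in ("OS_event", "DMFS_event"):
            bad_flags = set(df[col].dropna()) - {0, 1}
            if bad_flags:
                raise TableValidationError(f"invalid {col} flags: {sorted(bad_flags)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class CopyNumberTable:
    """Discrete per-gene, per-sample copy-number calls in {-2,-1,0,+1,+2}."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index.astype(str), "gene symbol")
        _check_unique(df.columns.astype(str), "sample id")
        arr = df.to_numpy()
        bad = ~np.isin(arr, CNA_ALPHABET)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise TableValidationError(
                f"invalid copy-number call {arr[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CellLinePanel:
    """A drug-sensitivity panel: per-line EC50 (uM) and log2 expression.

    ``expression`` holds genes in rows and cell lines in columns, already on
    log2 scale (microarray/RNA-seq convention for cell-line compendia).
    """

    ec50: pd.Series
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.ec50.index.astype(str), "cell line id")
        if (self.ec50 <= 0).any():
            line = self.ec50.index[self.ec50 <= 0][0]
            raise TableValidationError(f"non-positive EC50 for line {line!r}")
        if list(self.expression.columns) != list(self.ec50.index):
            raise TableValidationError(
                "panel expression columns do not match EC50 line ids"
            )
        _check_unique(self.expression.index.astype(str), "gene symbol")

    @property
    def lines(self) -> list[str]:
        return list(self.ec50.index)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)


@dataclass(frozen=True)
class GeneList:
    """A named, ordered, duplicate-free list of gene symbols.

    ``criterion`` records, as free text, which selection rule produced the
    list (its provenance inside a pipeline run).
    """

    name: str
    symbols: tuple[str, ...]
    criterion: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise TableValidationError("gene list name must be non-empty")
        _check_unique(self.symbols, f"symbol in gene list {self.name!r}")
        object.__setattr__(self, "symbols", tuple(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.symbols

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "criterion": self.criterion,
            "symbols": list(self.symbols),
        }


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_gene_table(path: str | Path, value_kind: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene":
        raise TableValidationError(
            f"{path}: first column must be 'gene', got {df.columns[0]!r}"
        )
    if df.isna().any().any():
        r = int(np.argwhere(df.isna().to_numpy())[0][0])
        raise TableValidationError(f"{path}: ragged or missing value in row {r + 2}")
    out = df.set_index("gene")
    out.index.name = None
    try:
        out = out.astype(float if value_kind == "float" else int)
    except ValueError as exc:
        raise TableValidationError(f"{path}: non-numeric value ({exc})") from exc
    return out


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows FPKM TSV (first column ``gene``)."""
    return ExpressionMatrix(_read_gene_table(path, "float"))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_cna(path: str | Path) -> CopyNumberTable:
    return CopyNumberTable(_read_gene_table(path, "int"))


def write_cna(table: CopyNumberTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if df.columns[0] != "sample":
        raise TableValidationError(
            f"{path}: first column must be 'sample', got {df.columns[0]!r}"
        )
    df = df.set_index("sample")
    for col in ("OS_time", "DMFS_time"):
        df[col] = pd.to_numeric(df[col])
    for col in ("OS_event", "DMFS_event"):
        df[col] = df[col].astype(int)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample")


def read_panel(path: str | Path) -> CellLinePanel:
    """Read a cell-line panel TSV.

    The on-disk layout is genes in rows (first column ``gene``) plus one
    reserved row named ``EC50`` holding the per-line EC50 values in uM.
    """
    df = _read_gene_table(path, "float")
    if "EC50" not in df.index:
        raise TableValidationError(f"{path}: panel file missing 'EC50' row")
    ec50 = df.loc["EC50"]
    expr = df.drop(index="EC50")
    return CellLinePanel(ec50=ec50, expression=expr)


def write_panel(panel: CellLinePanel, path: str | Path) -> None:
    out = pd.concat([panel.ec50.to_frame("EC50").T, panel.expression])
    out.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path, name: str | None = None,
                   criterion: str = "") -> GeneList:
    """Read a one-symbol-per-line text file (or JSON with provenance)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return GeneList(
            name=payload["name"],
            symbols=tuple(payload["symbols"]),
            criterion=payload.get("criterion", ""),
        )
    symbols = tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return GeneList(name=name or path.stem, symbols=symbols, criterion=criterion)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(gene_list.to_dict(), indent=2) + "\n")
    else:
        path.write_text("\n".join(gene_list.symbols) + "\n")


# ---------------------------------------------------------------------------
# Transformations and sample selection
# ---------------------------------------------------------------------------

def log2_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(FPKM + 1); the +1 pseudocount handles FPKM = 0."""
    return np.log2(matrix.values + 1.0)


def zscore(matrix: ExpressionMatrix) -> ZScoreMatrix:
    """Per-gene z-scores of log2(FPKM+1) over all supplied samples.

    The reference distribution is the full set of samples in ``matrix``
    ("overall distribution" referencing), with population (ddof=0) standard
    deviation. Genes with zero variance map to all-zero rows.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    log2 = log2_fpkm(matrix).to_numpy()
    mu = log2.mean(axis=1, keepdims=True)
    sd = log2.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (log2 - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return ZScoreMatrix(
        pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns)
    )


def select_tnbc(clinical: ClinicalTable) -> list[str]:
    """Samples negative for all of ER, PR and HER2 by IHC.

    An ``unknown`` status in any receptor excludes the sample: triple
    negativity must be established, not merely not contradicted.
    """
    df = clinical.values
    mask = (
        (df["ER"] == "negative")
        & (df["PR"] == "negative")
        & (df["HER2"] == "negative")
    )
    return list(df.index[mask])
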