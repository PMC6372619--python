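"""Readers and writers for expression matrices, control lists, and GCT files.

All tabular matrices follow the field convention: variables (genes) in rows,
samples in columns.  TSV/CSV files carry the gene identifier in the first
column and sample identifiers in the header row; GCT files follow the
Broad 1.2 / 1.3 dialects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "read_controls",
    "resolve_controls",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample control flags.

    Parameters
    ----------
    data : pandas.DataFrame
        Dense numeric matrix, genes in rows, samples in columns.
    control_mask : numpy.ndarray of bool
        One flag per sample column; ``True`` marks a control (vehicle) sample.
    """

    data: pd.DataFrame
    control_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.control_mask is None:
            self.control_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.control_mask.shape != (self.data.shape[1],):
            raise ValueError(
                f"control_mask length {self.control_mask.shape} does not match "
                f"{self.data.shape[1]} samples"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            _raise_non_numeric(self.data)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def control_ids(self) -> list:
        return list(self.data.columns[self.control_mask])


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(set(index[index.duplicated()]))
        raise ValueError(f"duplicate {what} ids: {dups}")


def _raise_non_numeric(df: pd.DataFrame) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
    raise ValueError("matrix contains non-numeric values")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_matrix(path, fmt: str | None = None, controls=None) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV, CSV, or GCT.

    Parameters
    ----------
    path : str or Path
        Input file.  The format is inferred from the suffix unless `fmt`
        is given explicitly (one of ``"tsv"``, ``"csv"``, ``"gct"``).
    controls : iterable of str, str (path), or None
        Sample ids to flag as controls, or a path to a one-id-per-line file.
        Unknown ids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "gct":
        df = _read_gct(path)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    mask = resolve_controls(df.columns, controls)
    return ExpressionMatrix(df, mask)


def resolve_controls(sample_ids, controls) -> np.ndarray:
    """Build a boolean control mask from ids, a file path, or regex patterns.

    Each entry is matched as an exact sample id first; an entry matching no
    id exactly is retried as a regular expression (full match).
    """
    sample_ids = pd.Index(sample_ids)
    mask = np.zeros(len(sample_ids), dtype=bool)
    if controls is None:
        return mask
    if isinstance(controls, (str, Path)):
        controls = read_controls(controls)
    for entry in controls:
        entry = str(entry)
        hit = sample_ids == entry
        if not hit.any():
            try:
                pat = re.compile(entry)
            except re.error:
                pat = None
            if pat is not None:
                hit = np.array([bool(pat.fullmatch(s)) for s in sample_ids])
        if not hit.any():
            raise ValueError(f"unknown control sample id or pattern: {entry!r}")
        mask |= hit
    return mask


def read_controls(path) -> list[str]:
    """Read a control-id file: one sample id per line, blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError("malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        # 1.3 adds counts of row/column metadata fields
        n_rmeta = int(dims[2]) if version == "#1.3" and len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if version == "#1.3" and len(dims) > 3 else 0
        df = pd.read_csv(fh, sep="\t", index_col=0)
    # drop the Description column (1.2) / row-metadata columns (1.3)
    n_meta_cols = 1 if version == "#1.2" else n_rmeta
    if n_cmeta:
        df = df.iloc[n_cmeta:]
    df = df.iloc[:, n_meta_cols:]
    if df.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT dimension mismatch: header says {n_rows}x{n_cols}, "
            f"body is {df.shape[0]}x{df.shape[1]}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(data, path, fmt: str | None = None) -> None:
    """Write a genes x samples matrix (DataFrame or ExpressionMatrix)."""
    if isinstance(data, ExpressionMatrix):
        data = data.data
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{data.shape[0]}\t{data.shape[1]}\n")
            out = data.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        sep = "," if fmt == "csv" else "\t"
        out = data.copy()
        out.index.name = out.index.name or "gene"
        out.to_csv(path, sep=sep)
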