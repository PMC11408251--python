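"""Tab-delimited readers and writers for the pipeline's file dialects.

Expression matrices: features x samples TSV whose first column is the
feature id, second column the gene symbol, remaining columns one per
sample. Mouse matrices carry group labels in a companion samples TSV
(``sample_id``, ``group``). Phenotypes: subjects x variables TSV indexed by
``subject_id``. Methylation: CpGs x subjects TSV indexed by ``cpg_id`` with
an optional ``region`` annotation column. All readers validate headers,
duplicate ids and numeric cells and fail with informative messages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_methylation",
    "write_methylation",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iloc[r, c]!r}"
        )
    return out


def write_expression(
    expr: ExpressionMatrix, path: str | Path, groups_path: str | Path | None = None
) -> None:
    out = expr.values.copy()
    out.insert(0, "symbol", expr.symbols)
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t")
    if groups_path is not None:
        if expr.groups is None:
            raise ValueError("matrix has no group labels to write")
        g = expr.groups.rename("group").to_frame()
        g.index.name = "sample_id"
        g.to_csv(groups_path, sep="\t")


def read_expression(
    path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected feature id, symbol and >=1 sample column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated feature id {dup!r}")
    df = df.set_index(id_col)
    symbols = df.pop("symbol") if "symbol" in df.columns else df.pop(df.columns[0])
    values = _to_numeric(df, path)
    groups = None
    if groups_path is not None:
        g = _read_tsv(groups_path)
        if g.columns[0] != "sample_id" or "group" not in g.columns:
            raise ValueError(f"{groups_path}: expected columns sample_id, group")
        if g["sample_id"].duplicated().any():
            dup = g["sample_id"][g["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"{groups_path}: duplicated sample id {dup!r}")
        groups = g.set_index("sample_id")["group"]
    return ExpressionMatrix(values=values, symbols=symbols.rename("symbol"), groups=groups)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    out = pheno.copy()
    out.index.name = out.index.name or "subject_id"
    out.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id, got {df.columns[0]!r}")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated subject id {dup!r}")
    df = df.set_index("subject_id")
    for col in df.columns:
        if col == "diagnosis":
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_methylation(meth: pd.DataFrame, path: str | Path) -> None:
    out = meth.copy()
    out.index.name = out.index.name or "cpg_id"
    out.to_csv(path, sep="\t")


def read_methylation(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated CpG id {dup!r}")
    df = df.set_index(id_col)
    if "region" in df.columns:
        df = df.drop(columns=["region"])
    values = _to_numeric(df, path)
    arr = values.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError(f"{path}: beta values must lie in [0, 1]")
    return values
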