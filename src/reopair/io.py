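"""Plain-text I/O: expression/CNV matrices (TSV and MTX triplet with name
sidecars), label and survival tables, YAML configs.

Matrices are stored genes-in-rows everywhere; the first TSV column is the
gene ID.  Floats are written with 10 significant digits so text outputs are
byte-stable across runs and platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    pass


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_name: str = "gene") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene ID {dup!r}")
    return df


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """Write <prefix>.mtx plus <prefix>.rows / <prefix>.cols name sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(matrix.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(map(str, matrix.index)) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(map(str, matrix.columns)) + "\n")


def read_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape != (len(rows), len(cols)):
        raise ParseError(
            f"{prefix}: matrix shape {dense.shape} does not match sidecars "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    if len(set(rows)) != len(rows):
        raise ParseError(f"{prefix}: duplicate gene IDs in row sidecar")
    return pd.DataFrame(dense, index=rows, columns=cols)


def read_expression(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix (``fmt`` in {tsv, mtx})."""
    if fmt == "tsv":
        return read_matrix_tsv(path)
    if fmt == "mtx":
        return read_matrix_mtx(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_series_tsv(series: pd.Series, path: str | Path, index_name: str = "id") -> None:
    df = series.rename_axis(index_name).reset_index()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_labels_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name=df.columns[1])


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing survival columns {sorted(missing)}")
    return df


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
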