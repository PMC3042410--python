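"""TSV readers and writers for the pipeline's tables.

All files are UTF-8, tab-separated, with a header row; lines starting with
``#`` are comments.  Expression matrices carry their scale in a
``#scale=`` comment line; probe-level matrices have ``probe_id`` and
``gene_id`` as the first two columns, gene-level matrices start at
``gene_id``.  Group-summarized matrices encode (strain, fraction, project)
column keys as ``strain|fraction|project``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polyte.normalize import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sheet",
    "write_sheet",
    "read_features",
    "write_features",
    "read_ct",
    "write_te_table",
    "read_te_table",
    "read_config",
]

SHEET_COLUMNS = ["array_id", "strain", "fraction", "project", "tech_rep"]


class ParseError(ValueError):
    pass


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=None)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc


def _scale_from_header(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#scale="):
                return line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    return "linear"


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    df = matrix.data.copy()
    if isinstance(df.columns, pd.MultiIndex):
        df.columns = ["|".join(map(str, c)) for c in df.columns]
    df = df.reset_index()
    if matrix.gene_map is not None:
        df.insert(1, "gene_id", matrix.gene_map.to_numpy())
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix(path) -> ExpressionMatrix:
    scale = _scale_from_header(path)
    df = _read_tsv(path)
    first = df.columns[0]
    gene_map = None
    if first == "probe_id" and "gene_id" in df.columns[:2]:
        df = df.set_index("probe_id")
        gene_map = df.pop("gene_id")
    else:
        df = df.set_index(first)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2  # header + 1-based
        raise ParseError(f"{path}: duplicate row id {dup!r} (line ~{line})")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ParseError(f"{path}: non-numeric intensity columns {bad}")
    if any("|" in str(c) for c in df.columns):
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(str(c).split("|")) for c in df.columns],
            names=["strain", "fraction", "project"],
        )
    return ExpressionMatrix(df, scale=scale, gene_map=gene_map)


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["array_id"].duplicated().any():
        dup = df.loc[df["array_id"].duplicated(), "array_id"].iloc[0]
        raise ParseError(f"{path}: duplicate array_id {dup!r}")
    df["project"] = df["project"].astype(str)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    out = features.copy()
    if "categories" in out.columns:
        out["categories"] = out["categories"].map(
            lambda c: ";".join(sorted(c)) if not isinstance(c, str) else c
        )
    out.to_csv(path, sep="\t", index=True)


def read_features(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("gene_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    if "categories" in df.columns:
        df["categories"] = df["categories"].map(
            lambda c: set(str(c).split(";")) if pd.notna(c) else set()
        )
    return df


def read_ct(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"gene_id", "strain", "fraction", "target", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: Ct table missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["ct"]):
        raise ParseError(f"{path}: non-numeric ct values")
    return df


def write_te_table(te_table: pd.DataFrame, path) -> None:
    te_table.to_csv(path, sep="\t", index=True)


def read_te_table(path) -> pd.DataFrame:
    return _read_tsv(path).set_index("gene_id")


def read_config(path) -> dict:
    """Read a structured (YAML) configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg
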