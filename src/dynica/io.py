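"""Delimited-text readers and writers for every pipeline artifact.

All tables are tab-separated text.  Files written by the pipeline start with
``#``-prefixed header comments recording the package version, the seed and a
digest of the inputs, so any stage can be rerun from its written artifacts.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _header_lines(meta: dict | None) -> str:
    meta = {"version": __version__, **(meta or {})}
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_matrix(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Matrix as TSV: first column = promoter/component ids, '#' metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        # %.17g round-trips float64 exactly, so downstream stages rerun from
        # written artifacts reproduce in-line results bit for bit
        df.to_csv(fh, sep="\t", float_format="%.17g")


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col,
        float_precision="round_trip",
    )


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Long-format table (no index column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


def read_series(path) -> pd.DataFrame:
    """Long-format fluorescence series (promoter_id, time_min, fluorescence,
    background)."""
    df = read_table(path)
    df["promoter_id"] = df["promoter_id"].astype(str)
    return df


def read_annotations(path) -> pd.DataFrame:
    """Promoter -> functional category table (promoter_id, category)."""
    df = read_table(path)
    df["promoter_id"] = df["promoter_id"].astype(str)
    return df
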