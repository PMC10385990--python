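"""Shared tabular I/O helpers.

All tabular artifacts are plain TSV.  Files written by the pipeline carry
``#``-prefixed metadata header lines (parameters, package version) which are
transparently skipped on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd


def write_tsv(
    df: pd.DataFrame,
    path: str | os.PathLike,
    metadata: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    """Write a DataFrame as TSV with optional '#' metadata header lines."""
    path = os.fspath(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, index_col: int | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping '#' header lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes × samples count matrix (first column = gene identifier)."""
    counts = read_tsv(path, index_col=0)
    if counts.shape[1] < 2:
        raise ValueError(f"count matrix {path!r} has fewer than 2 sample columns")
    return counts


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an externally produced differential-expression table.

    Expected columns: ``gene``, ``logFC``, ``pvalue`` (extra columns are
    ignored).  Returns a DataFrame indexed by gene with columns
    ``logFC``/``pvalue``.
    """
    df = read_tsv(path)
    missing = {"gene", "logFC", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(
            f"DE table {path!r} is missing required columns: {sorted(missing)}"
        )
    return df.set_index("gene")[["logFC", "pvalue"]]


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the long-format sample metadata table.

    One row per sample with columns ``contrast_id``, ``species``, ``tissue``,
    ``compound``, ``sample``, ``group``.
    """
    df = read_tsv(path)
    required = {"contrast_id", "species", "tissue", "compound", "sample", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path!r} missing columns: {sorted(missing)}")
    return df


def contrast_metadata(sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample metadata to one row per contrast."""
    return (
        sample_meta[["contrast_id", "species", "tissue", "compound"]]
        .drop_duplicates("contrast_id")
        .set_index("contrast_id")
    )


def write_lines(lines: Iterable[str], path: str | os.PathLike) -> None:
    path = os.fspath(path)
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
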