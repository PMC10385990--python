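"""Ortholog mapping of species-level signatures into the reference space.

Two input routes: curated ortholog tables (source gene, target gene,
confidence score) or pairwise-similarity hit tables (BLAST tabular,
outfmt-6-style) from which reciprocal best hits are computed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sigmeta.designature import ContrastSignature

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-5

ORTHOLOG_COLUMNS = ["source_gene", "target_gene", "score"]
HIT_COLUMNS = ["query_id", "subject_id", "evalue", "bitscore"]


@dataclass
class MappingReport:
    """Bookkeeping for one signature's ortholog conversion."""

    contrast_id: str
    n_in: int
    n_mapped: int
    n_collapsed: int

    def to_dict(self) -> dict:
        return {
            "contrast_id": self.contrast_id,
            "n_in": self.n_in,
            "n_mapped": self.n_mapped,
            "n_collapsed": self.n_collapsed,
        }


def load_ortholog_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate a (source_gene, target_gene, score) TSV.

    The file may be headerless or carry the canonical header.  Duplicated
    (source, target) pairs are deduplicated (keeping the best score) with a
    warning; malformed rows raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:3] == ORTHOLOG_COLUMNS:
                continue  # header
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
            if not np.isfinite(score) or score < 0:
                raise ValueError(f"{path}:{lineno}: score must be finite and >= 0")
            rows.append((fields[0], fields[1], score))
    table = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    n_dupes = int(table.duplicated(["source_gene", "target_gene"]).sum())
    if n_dupes:
        logger.warning(
            "%s: %d duplicated (source, target) pair(s) collapsed", path, n_dupes
        )
        table = (
            table.sort_values("score", ascending=False)
            .drop_duplicates(["source_gene", "target_gene"])
            .sort_index()
            .reset_index(drop=True)
        )
    return table


def load_hit_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read BLAST tabular (outfmt 6) hits: columns 1, 2, 11, 12.

    Keeps qseqid, sseqid, evalue and bitscore; the intervening alignment
    statistics are ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected >= 12 BLAST outfmt-6 columns, got {df.shape[1]}"
        )
    hits = df.iloc[:, [0, 1, 10, 11]].copy()
    hits.columns = HIT_COLUMNS
    return validate_hit_table(hits)


def validate_hit_table(hits: pd.DataFrame) -> pd.DataFrame:
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("evalues must be >= 0")
    if not np.isfinite(hits["bitscore"]).all():
        raise ValueError("bitscores must be finite")
    return hits


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: max bitscore, then min evalue, then
    lexicographically smallest subject_id."""
    ranked = hits.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
    )
    best = ranked.drop_duplicates("query_id")
    return best.set_index("query_id")[["subject_id", "bitscore"]]


def bbh_from_hits(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> pd.DataFrame:
    """Reciprocal (bidirectional) best hits from two hit tables.

    A pair (a, b) is emitted iff b is a's best forward hit and a is b's
    best reverse hit after discarding hits with evalue above the cutoff.
    The emitted confidence score is the mean of the two bitscores.  Output
    is 1:1 by construction.
    """
    forward = validate_hit_table(forward)
    reverse = validate_hit_table(reverse)
    fwd = forward[forward["evalue"] <= evalue_cutoff]
    rev = reverse[reverse["evalue"] <= evalue_cutoff]
    if fwd.empty or rev.empty:
        raise ValueError(
            f"no hits remain after filtering at evalue <= {evalue_cutoff:g}"
        )
    best_fwd = _best_hits(fwd)
    best_rev = _best_hits(rev)

    rows = []
    for query, (subject, bitscore) in best_fwd.iterrows():
        if subject in best_rev.index and best_rev.at[subject, "subject_id"] == query:
            rows.append(
                (query, subject, (bitscore + best_rev.at[subject, "bitscore"]) / 2.0)
            )
    table = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    return table.sort_values("source_gene").reset_index(drop=True)


def compose_tables(first: pd.DataFrame, second: pd.DataFrame) -> pd.DataFrame:
    """Two-hop ortholog conversion (e.g. species → intermediate → reference).

    Composed confidence is the min of the two hop scores (conservative).
    """
    merged = first.merge(
        second, left_on="target_gene", right_on="source_gene", suffixes=("_1", "_2")
    )
    out = pd.DataFrame(
        {
            "source_gene": merged["source_gene_1"],
            "target_gene": merged["target_gene_2"],
            "score": np.minimum(merged["score_1"], merged["score_2"]),
        }
    )
    return out.drop_duplicates(["source_gene", "target_gene"]).reset_index(drop=True)


def map_signature_to_reference(
    sig: ContrastSignature,
    table: pd.DataFrame,
    collapse: str = "max_abs",
) -> tuple[ContrastSignature, MappingReport]:
    """Convert a species-level signature to reference gene identifiers.

    Each source gene follows its highest-score target (the "most likely"
    ortholog; ties resolved to the lexicographically smallest target).  When
    several source genes land on one target the retained score is, by
    default, the one with maximum |s| (ties → the more positive) —
    preserving the strongest evidence; ``collapse="mean"`` averages
    instead.  Unmapped genes are dropped and counted in the report.
    """
    if table.empty:
        raise ValueError("ortholog table is empty")
    if collapse not in ("max_abs", "mean"):
        raise ValueError(f"unknown collapse rule {collapse!r}")

    best_target = (
        table.sort_values(
            ["source_gene", "score", "target_gene"], ascending=[True, False, True]
        )
        .drop_duplicates("source_gene")
        .set_index("source_gene")["target_gene"]
    )
    mapped = sig.scores.rename(index=best_target.to_dict())
    mapped = mapped[mapped.index.isin(set(best_target.values))]
    n_in = len(sig.scores)
    n_mapped = len(mapped)
    if n_mapped == 0:
        raise ValueError(
            f"no genes of signature {sig.contrast_id!r} could be mapped"
        )

    if collapse == "mean":
        collapsed = mapped.groupby(level=0).mean()
    else:
        # max |s|, ties broken toward the more positive value
        frame = pd.DataFrame({"gene": mapped.index, "s": mapped.to_numpy()})
        frame["abs_s"] = frame["s"].abs()
        collapsed = (
            frame.sort_values(["gene", "abs_s", "s"], ascending=[True, False, False])
            .drop_duplicates("gene")
            .set_index("gene")["s"]
        )
    collapsed = collapsed.sort_index()
    collapsed.name = sig.scores.name
    report = MappingReport(
        contrast_id=sig.contrast_id,
        n_in=n_in,
        n_mapped=n_mapped,
        n_collapsed=n_mapped - len(collapsed),
    )
    if report.n_collapsed:
        logger.info(
            "%s: %d source genes collapsed onto shared targets",
            sig.contrast_id,
            report.n_collapsed,
        )
    return replace(sig, scores=collapsed), report
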