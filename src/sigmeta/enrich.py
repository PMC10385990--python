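"""Permutation gene set enrichment on contrast signatures.

Genes are ranked by signature score (descending, ties broken by gene id
for determinism) and each set is scored with the weighted
Kolmogorov–Smirnov running-sum extremum (weight exponent 1, |s| weights).
The null distribution comes from gene-label permutations — random
placements of the set over the ranked list — shared across all sets of the
same size within a contrast.  When the number of possible placements does
not exceed ``n_perm`` the null is enumerated exhaustively; otherwise it is
sampled, and each sampled placement is paired with its rank-mirrored
placement so the null is exactly symmetric under signature negation (this
makes ES, NES and p antisymmetric, and halves the number of draws needed).

NES = ES / mean(|null ES of the matching sign|), the standard
sign-conditional normalization; permutation p-values are sign-conditional
with the add-one (+1) correction.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from sigmeta.designature import ContrastSignature
from sigmeta.integrate import bh_adjust, stouffer_integrate_matrix, z_to_p
from sigmeta.simulate import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


def parse_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> gene...).

    Within-set duplicate genes are removed; duplicate set names or lines
    with fewer than three fields raise with the offending line number.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = tuple(dict.fromkeys(fields[2:]))
    return GeneSetCollection(sets=sets, source=os.fspath(path))


def _rank_signature(scores: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Rank genes by score descending, ties broken by gene id ascending."""
    frame = scores.rename("s").rename_axis("gene").reset_index()
    frame = frame.sort_values(["s", "gene"], ascending=[False, True])
    return frame["gene"].to_numpy(), frame["s"].to_numpy(dtype=float)


def _es_from_positions(pos: np.ndarray, absvals: np.ndarray) -> np.ndarray:
    """Weighted KS enrichment score for hit-position sets.

    Parameters
    ----------
    pos
        (B, k) array of 0-based ranks of the set members, sorted ascending
        along the last axis.  A single set may be passed as shape (k,).
    absvals
        |score| per rank of the full ranked list (length N).

    Returns the signed running-sum extremum for each of the B placements.
    """
    single = pos.ndim == 1
    pos2 = np.atleast_2d(pos)
    B, k = pos2.shape
    N = absvals.size
    if k >= N:
        raise ValueError("gene set must be smaller than the ranked universe")

    w = absvals[pos2]
    W = w.sum(axis=1, keepdims=True)
    flat = W[:, 0] == 0  # degenerate all-zero weights: fall back to equal
    if flat.any():
        w = np.where(flat[:, None], 1.0, w)
        W = np.where(flat[:, None], float(k), W)
    hit_cum = np.cumsum(w, axis=1) / W
    miss = (pos2 - np.arange(k)) / float(N - k)
    after = hit_cum - miss  # running sum right after each hit
    before = (hit_cum - w / W) - miss  # right before each hit
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    # exact |max| == |min| ties (structural in small universes, where both
    # extrema are multiples of 1/(N-k)) resolve to the positive extremum;
    # the tolerance absorbs accumulation-order rounding
    es = np.where(max_dev >= -min_dev - 1e-12, max_dev, min_dev)
    return es[0] if single else es


def _null_positions(
    N: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null hit placements: exhaustive when feasible, else sampled+mirrored."""
    if comb(N, k) <= n_perm:
        return np.array(list(combinations(range(N), k)), dtype=np.int64)
    draws = np.empty((n_perm, k), dtype=np.int64)
    for b in range(n_perm):
        draws[b] = rng.choice(N, size=k, replace=False)
    draws.sort(axis=1)
    mirrored = np.sort(N - 1 - draws, axis=1)
    return np.vstack([draws, mirrored])


def _nes_and_p(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """Sign-conditional NES and permutation p for one observed ES."""
    if es == 0:
        return 0.0, 1.0
    same_sign = null_es > 0 if es > 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same > 0:
        denom = float(np.abs(null_es[same_sign]).mean())
    else:  # no null of this sign observed: fall back to the full pool
        denom = float(np.abs(null_es).mean()) if null_es.size else np.nan
    nes = es / denom if denom else np.nan
    extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1.0 + extreme) / (1.0 + n_same)
    return nes, p


@dataclass
class _RankedContrast:
    """Cached ranking plus per-size null ES pools for one signature."""

    genes: np.ndarray
    absvals: np.ndarray
    rank_of: dict[str, int]
    n_perm: int
    rng: np.random.Generator
    _nulls: dict[int, np.ndarray]

    @classmethod
    def from_signature(
        cls, sig: ContrastSignature, n_perm: int, seed: int
    ) -> "_RankedContrast":
        genes, values = _rank_signature(sig.scores)
        return cls(
            genes=genes,
            absvals=np.abs(values),
            rank_of={g: i for i, g in enumerate(genes)},
            n_perm=n_perm,
            rng=np.random.default_rng(seed),
            _nulls={},
        )

    @property
    def n_genes(self) -> int:
        return self.genes.size

    def positions(self, members: tuple[str, ...]) -> np.ndarray:
        pos = sorted(self.rank_of[g] for g in members if g in self.rank_of)
        return np.asarray(pos, dtype=np.int64)

    def null_es(self, k: int) -> np.ndarray:
        if k not in self._nulls:
            pos = _null_positions(self.n_genes, k, self.n_perm, self.rng)
            self._nulls[k] = _es_from_positions(pos, self.absvals)
        return self._nulls[k]

    def score_set(self, members: tuple[str, ...]) -> tuple[float, float, float, int]:
        """(ES, NES, p, n_present) for one gene set."""
        pos = self.positions(members)
        k = pos.size
        es = float(_es_from_positions(pos, self.absvals))
        nes, p = _nes_and_p(es, self.null_es(k))
        return es, nes, p, k


def gsea_contrast(
    sig: ContrastSignature,
    sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Run permutation GSEA for every set against one signature.

    Returns a DataFrame indexed by set name with columns ES, NES, pval and
    n_present.  Sets with fewer than ``min_size`` or more than ``max_size``
    members present in the signature get an all-NaN row (insufficient
    pathway genes), mirroring the reporting convention for under-covered
    sets.
    """
    if len(sig.scores) == 0:
        raise ValueError("signature is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    ranked = _RankedContrast.from_signature(sig, n_perm, seed)
    rows = {}
    n_scored = 0
    for name, members in sets.sets.items():
        pos = ranked.positions(members)
        k = pos.size
        if k < min_size or k > max_size:
            rows[name] = (np.nan, np.nan, np.nan, k)
            continue
        rows[name] = ranked.score_set(members)
        n_scored += 1
    if n_scored == 0:
        logger.warning(
            "%s: no gene set within [%d, %d] present genes",
            sig.contrast_id,
            min_size,
            max_size,
        )
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ES", "NES", "pval", "n_present"]
    )
    table.index.name = "set"
    table["n_present"] = table["n_present"].astype(int)
    return table


def integrate_pathways(
    tables: dict[str, pd.DataFrame], weights: pd.Series
) -> pd.DataFrame:
    """Stouffer-integrate per-contrast NES into per-set Z, p and BH q.

    NES values are treated as approximately standard normal for the
    integration (documented caveat: the permutation NES is only
    asymptotically normal-calibrated).  Sets missing from every contrast
    are dropped with a warning.
    """
    if not tables:
        raise ValueError("no enrichment tables supplied")
    nes = pd.DataFrame({cid: t["NES"] for cid, t in tables.items()})
    empty = nes.isna().all(axis=1)
    if empty.any():
        logger.warning(
            "%d set(s) without any usable NES dropped: %s",
            int(empty.sum()),
            list(nes.index[empty])[:5],
        )
        nes = nes.loc[~empty]
    if nes.empty:
        raise ValueError("every set is missing from every contrast")
    Z = stouffer_integrate_matrix(nes, weights.reindex(nes.columns))
    p = z_to_p(Z.to_numpy())
    out = pd.DataFrame(
        {"Z": Z, "p": p, "q": bh_adjust(p), "n_contrasts": nes.notna().sum(axis=1)}
    )
    out.index.name = "set"
    return out
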