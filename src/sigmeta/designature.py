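"""Per-contrast differential expression and signed significance signatures.

The signature of a contrast assigns each gene the score

    s = -log10(p) * sign(log FC)

positive for significantly up-regulated genes, negative for significantly
down-regulated ones, with magnitude proportional to significance.

The built-in DE engine is a deliberately simple, documented stand-in for
heavyweight count-model packages: library-size normalization, log2 with a
0.5 pseudocount, and an empirical-Bayes-moderated t-test (gene variances
shrunk toward the mean gene variance with a prior of 4 degrees of freedom).
Externally produced DE tables (gene, logFC, pvalue) are accepted on equal
footing — the pipeline's contribution starts at the signature, not at the
DE engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

#: Smallest p-value admitted before taking log10; common DE tools underflow
#: to exactly 0, which would give an infinite signature.
P_FLOOR = 1e-300

#: Largest attainable |signature| given the p-value floor.
SIGNATURE_CAP = 300.0

MIN_REPLICATES = 3
PRIOR_DF = 4.0


@dataclass
class ContrastSignature:
    """Per-gene signed significance scores for one contrast."""

    scores: pd.Series  # index: gene id; values: s
    contrast_id: str
    species: str | None = None
    tissue: str | None = None
    compound: str | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError(
                f"duplicate gene identifiers in signature {self.contrast_id!r}"
            )

    def __len__(self) -> int:
        return len(self.scores)

    def negated(self) -> "ContrastSignature":
        return replace(self, scores=-self.scores)


@dataclass
class SignatureMatrix:
    """Reference genes × contrasts score matrix with contrast metadata.

    Entries are NaN where a gene is absent from a contrast's platform or
    species — missing, not zero.
    """

    values: pd.DataFrame  # genes × contrasts
    meta: pd.DataFrame  # index contrast_id; columns species, tissue, compound

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in signature matrix")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("contrast metadata does not align with matrix columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.values.shape[1]


def _normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalization preserving the mean library size."""
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts / libsize * libsize.mean()


def compute_differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    treated: str | None = None,
    prior_df: float = PRIOR_DF,
) -> pd.DataFrame:
    """Two-group moderated t-test DE on a count matrix.

    Parameters
    ----------
    counts
        Genes × samples nonnegative count matrix.
    groups
        Two-level sample labels aligned with ``counts`` columns.
    treated
        Label of the treated group.  Defaults to ``"treated"`` when present,
        otherwise the lexicographically larger level.

    Returns
    -------
    DataFrame indexed by gene with columns ``logFC`` (log2, treated vs
    control) and ``pvalue``.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if treated is None:
        treated = "treated" if "treated" in levels else levels[1]
    elif treated not in levels:
        raise ValueError(f"treated level {treated!r} not among {levels}")
    control = next(lv for lv in levels if lv != treated)

    n_trt = int((groups == treated).sum())
    n_ctl = int((groups == control).sum())
    if min(n_trt, n_ctl) < MIN_REPLICATES:
        raise ValueError(
            f"groups of size {n_ctl} ({control!r}) and {n_trt} ({treated!r}): "
            f"at least {MIN_REPLICATES} replicates per group are required"
        )
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")

    norm = _normalize_counts(counts)
    trt = norm.loc[:, groups == treated].to_numpy(dtype=float)
    ctl = norm.loc[:, groups == control].to_numpy(dtype=float)

    logfc = np.log2(trt.mean(axis=1) + 0.5) - np.log2(ctl.mean(axis=1) + 0.5)

    log_trt = np.log2(trt + 0.5)
    log_ctl = np.log2(ctl + 0.5)
    delta = log_trt.mean(axis=1) - log_ctl.mean(axis=1)
    df_resid = n_trt + n_ctl - 2
    ss = log_trt.var(axis=1, ddof=1) * (n_trt - 1) + log_ctl.var(axis=1, ddof=1) * (
        n_ctl - 1
    )
    s2 = ss / df_resid
    # Empirical-Bayes moderation: shrink gene variances toward a common
    # prior variance with prior_df pseudo-observations.  The prior is the
    # geometric mean of gene variances (variance priors live on the log
    # scale); an arithmetic-mean prior overweights the skewed upper tail
    # and makes the integrated null measurably conservative.
    s2_prior = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300)))))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_mod * (1.0 / n_trt + 1.0 / n_ctl))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t = np.where((delta == 0) & (se == 0), 0.0, t)
    pvalue = 2.0 * stats.t.sf(np.abs(t), df_resid + prior_df)
    pvalue = np.where(np.isfinite(t), pvalue, 0.0)

    return pd.DataFrame({"logFC": logfc, "pvalue": pvalue}, index=counts.index)


def signature_from_de(
    de: pd.DataFrame,
    contrast_id: str = "contrast",
    species: str | None = None,
    tissue: str | None = None,
    compound: str | None = None,
) -> ContrastSignature:
    """Transform a DE table into the signed significance signature.

    ``s = -log10(p) * sign(logFC)`` with p floored at 1e-300 (so |s| <= 300)
    and ``s = 0`` wherever ``logFC = 0``.  Genes with missing p-values are
    dropped rather than imputed.
    """
    de = de.dropna(subset=["pvalue"])
    p = de["pvalue"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    s = -np.log10(np.maximum(p, P_FLOOR)) * np.sign(de["logFC"].to_numpy(dtype=float))
    scores = pd.Series(s, index=de.index, name=contrast_id)
    return ContrastSignature(
        scores=scores,
        contrast_id=contrast_id,
        species=species,
        tissue=tissue,
        compound=compound,
    )


def build_signature_matrix(signatures: list[ContrastSignature]) -> SignatureMatrix:
    """Assemble per-contrast signatures into a genes × contrasts matrix.

    Genes are the union across contrasts; a gene absent from a contrast is
    NaN in that column.  Signatures must already live in the reference gene
    space (post ortholog mapping) and carry unique contrast ids.
    """
    if not signatures:
        raise ValueError("at least one signature is required")
    ids = [sig.contrast_id for sig in signatures]
    dupes = {cid for cid in ids if ids.count(cid) > 1}
    if dupes:
        raise ValueError(f"duplicate contrast_id(s): {sorted(dupes)}")
    values = pd.concat(
        [sig.scores.rename(sig.contrast_id) for sig in signatures], axis=1
    )
    values.index.name = "gene"
    meta = pd.DataFrame(
        {
            "species": [sig.species for sig in signatures],
            "tissue": [sig.tissue for sig in signatures],
            "compound": [sig.compound for sig in signatures],
        },
        index=pd.Index(ids, name="contrast_id"),
    )
    return SignatureMatrix(values=values, meta=meta)
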