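"""Correlation-based metabolite prediction from expression signatures.

A model is fit on a paired transcriptome/metabolome reference: per
metabolite, the Spearman correlation profile over all genes, summarized as
a positive (top-k) and a negative (bottom-k) gene set.  A contrast's
predicted metabolite response is the difference of the normalized
enrichment scores of the two sets against the contrast signature
(positive NES = predicted increase), studentized against its own
permutation null so per-contrast scores are variance-calibrated before
Stouffer integration across contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sigmeta.designature import ContrastSignature
from sigmeta.enrich import _nes_and_p, _RankedContrast
from sigmeta.integrate import bh_adjust, stouffer_integrate_matrix, z_to_p
from sigmeta.simulate import PairedReference

logger = logging.getLogger(__name__)

DEFAULT_K = 100
DEFAULT_N_PERM = 2_000
DEFAULT_MIN_SIZE = 5


@dataclass
class MetaboliteGeneModel:
    """Per-metabolite gene-correlation profiles and derived k-gene sets."""

    rho: pd.DataFrame  # metabolites × genes Spearman correlations
    positive_sets: dict[str, tuple[str, ...]]  # top-k by rho
    negative_sets: dict[str, tuple[str, ...]]  # bottom-k
    k: int

    @property
    def metabolites(self) -> list[str]:
        return list(self.rho.index)


def vst_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing-style normalization of a count matrix.

    Size factors are median-of-ratios against the per-gene geometric-mean
    reference (computed over genes with all-positive counts), rescaled to
    median 1 so an unperturbed sample has size factor 1; the output is
    ``log2(count / size_factor + 1)``.  When no gene has all-positive
    counts, library-size factors are used instead (with a warning).
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        logref = np.log(x[all_positive]).mean(axis=1, keepdims=True)
        ratios = np.log(x[all_positive]) - logref
        sf = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no gene with all-positive counts; falling back to library-size factors"
        )
        lib = x.sum(axis=0)
        sf = lib / np.exp(np.log(lib).mean())
    sf = sf / np.median(sf)
    out = np.log2(x / sf + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def fit_metabolite_model(
    ref: PairedReference, k: int = DEFAULT_K
) -> MetaboliteGeneModel:
    """Fit Spearman gene-correlation profiles on the paired reference.

    Ties in the correlation ranking are broken by gene id for determinism;
    constant metabolites are skipped with a warning.  Requires
    ``2k <= n_genes`` so the positive and negative sets stay disjoint.
    """
    if k < DEFAULT_MIN_SIZE:
        raise ValueError(f"k must be >= {DEFAULT_MIN_SIZE}")
    expr = ref.expression
    metab = ref.metabolites
    n_genes = expr.shape[0]
    if k > n_genes:
        raise ValueError(f"k ({k}) exceeds the number of genes ({n_genes})")
    if 2 * k > n_genes:
        raise ValueError("2k must not exceed the number of genes (disjoint sets)")

    constant = metab.nunique(axis=1) <= 1
    if constant.any():
        logger.warning(
            "skipping constant metabolite(s): %s", list(metab.index[constant])
        )
        metab = metab.loc[~constant]
    if metab.empty:
        raise ValueError("no non-constant metabolite to model")

    # Spearman = Pearson on ranks; compute via standardized rank matrices.
    n = expr.shape[1]
    gene_ranks = stats.rankdata(expr.to_numpy(), axis=1)
    met_ranks = stats.rankdata(metab.to_numpy(), axis=1)

    def standardize(r: np.ndarray) -> np.ndarray:
        centered = r - r.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = centered / sd
        return np.where(sd == 0, 0.0, z)  # constant genes get rho = 0

    rho = standardize(met_ranks) @ standardize(gene_ranks).T / n
    rho_df = pd.DataFrame(rho, index=metab.index, columns=expr.index)

    positive: dict[str, tuple[str, ...]] = {}
    negative: dict[str, tuple[str, ...]] = {}
    for metabolite, profile in rho_df.iterrows():
        ordered = profile.rename("rho").rename_axis("gene").reset_index()
        top = ordered.sort_values(["rho", "gene"], ascending=[False, True])
        bottom = ordered.sort_values(["rho", "gene"], ascending=[True, True])
        positive[metabolite] = tuple(top["gene"].head(k))
        negative[metabolite] = tuple(bottom["gene"].head(k))
    return MetaboliteGeneModel(
        rho=rho_df, positive_sets=positive, negative_sets=negative, k=k
    )


def _calibrated_nes_difference(
    ranked: _RankedContrast,
    pos_members: tuple[str, ...],
    neg_members: tuple[str, ...],
    min_size: int,
) -> float:
    """NES(positive set) - NES(negative set), studentized by its null SD.

    Each term reuses the enrichment machinery (shared per-size null pools).
    The difference of two sign-normalized NES values has null variance
    above 1, which would inflate downstream Stouffer Z-scores; dividing by
    the permutation-null SD of the same difference restores unit-variance
    calibration while preserving sign and antisymmetry.
    """
    d = 0.0
    var_null = 0.0
    n_terms = 0
    for members, factor in ((pos_members, 1.0), (neg_members, -1.0)):
        p = ranked.positions(members)
        if p.size < min_size:
            continue
        es = float(_es_from_pos(ranked, p))
        null = ranked.null_es(p.size)
        nes, _ = _nes_and_p(es, null)
        d += factor * nes
        # the two terms are independent under the permutation null, so the
        # null variance of the difference is the sum of the variances; the
        # variance is invariant under signature negation, keeping the
        # calibrated score exactly antisymmetric
        var_null += float(np.var(_normalize_null(null)))
        n_terms += 1
    if n_terms == 0:
        return float("nan")
    sd = np.sqrt(var_null)
    return d / sd if sd > 0 else float("nan")


def _es_from_pos(ranked: _RankedContrast, pos: np.ndarray) -> float:
    from sigmeta.enrich import _es_from_positions

    return float(_es_from_positions(pos, ranked.absvals))


def _normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Map a null ES pool onto the NES scale (sign-conditional means)."""
    pos = null_es > 0
    neg = null_es < 0
    out = np.zeros_like(null_es)
    if pos.any():
        out[pos] = null_es[pos] / np.abs(null_es[pos]).mean()
    if neg.any():
        out[neg] = null_es[neg] / np.abs(null_es[neg]).mean()
    return out


def predict_metabolites(
    sig: ContrastSignature,
    model: MetaboliteGeneModel,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.Series:
    """Per-metabolite predicted response scores for one contrast.

    Positive scores predict a metabolite increase.  A metabolite is NaN
    when both of its gene sets have fewer than ``min_size`` members present
    in the signature.
    """
    if not model.positive_sets:
        raise ValueError("metabolite model is empty")
    ranked = _RankedContrast.from_signature(sig, n_perm, seed)
    scores = {}
    for metabolite in model.metabolites:
        scores[metabolite] = _calibrated_nes_difference(
            ranked,
            model.positive_sets[metabolite],
            model.negative_sets[metabolite],
            min_size,
        )
    out = pd.Series(scores, name=sig.contrast_id)
    out.index.name = "metabolite"
    return out


def integrate_metabolites(
    predictions: dict[str, pd.Series], weights: pd.Series
) -> pd.DataFrame:
    """Stouffer-integrate per-contrast metabolite scores into Z, p, BH q."""
    if not predictions:
        raise ValueError("no predictions supplied")
    nes = pd.DataFrame(predictions)
    Z = stouffer_integrate_matrix(nes, weights.reindex(nes.columns))
    p = z_to_p(Z.to_numpy())
    out = pd.DataFrame(
        {"Z": Z, "p": p, "q": bh_adjust(p), "n_contrasts": nes.notna().sum(axis=1)}
    )
    out.index.name = "metabolite"
    return out
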