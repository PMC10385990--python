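"""Species-balanced weighted Stouffer integration of signature evidence.

Per-gene signatures are converted to standard-normal Z equivalents,
combined across contrasts as ``Z = sum(w_i z_i) / sqrt(sum(w_i^2))`` with
weights giving every species equal total representation, converted back to
two-tailed p-values, BH-adjusted, and classified into conserved-response
bands by integrated Z magnitude and cross-contrast signature standard
deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from sigmeta.designature import SIGNATURE_CAP, SignatureMatrix

DEFAULT_Z_HI = 10.0
DEFAULT_Z_LO = 5.0
DEFAULT_SD_CUT = 10.0
DEFAULT_MIN_SPECIES = 6

CLASSES = ("up_consistent", "up_high_sd", "down_consistent", "down_high_sd", "none")


def species_balanced_weights(meta: pd.DataFrame) -> pd.Series:
    """Per-contrast weights giving each species equal total weight.

    ``w(contrast) = 1 / (number of contrasts of its species)`` so the summed
    weight of every species is 1.
    """
    if "species" not in meta.columns:
        raise ValueError("contrast metadata must carry a 'species' column")
    species = meta["species"]
    if species.isna().any():
        missing = list(meta.index[species.isna()])
        raise ValueError(f"contrasts without species label: {missing}")
    counts = species.value_counts()
    w = 1.0 / species.map(counts).astype(float)
    w.name = "weight"
    return w


def signature_to_z(s):
    """Convert signed significance scores to standard-normal Z equivalents.

    A score of magnitude |s| encodes a two-tailed p of 10^(-|s|); the
    returned z is the matching signed two-tailed normal quantile:
    ``z = sign(s) * Phi^-1(1 - 10^(-|s|) / 2)``.  |s| is capped at 300.
    NaN passes through (missing entries stay missing).
    """
    s_arr = np.asarray(s, dtype=float)
    scalar = s_arr.ndim == 0
    mag = np.minimum(np.abs(s_arr), SIGNATURE_CAP)
    with np.errstate(over="ignore"):
        p_two = np.power(10.0, -mag)
    z = np.sign(s_arr) * stats.norm.isf(p_two / 2.0)
    z = np.where(np.isnan(s_arr), np.nan, z)
    return float(z) if scalar else z


def z_to_p(z):
    """Two-tailed standard-normal p, underflow-safe via erfc.

    Valid far into the tail (|Z| ~ 37+) without flushing to zero.
    """
    z_arr = np.asarray(z, dtype=float)
    p = special.erfc(np.abs(z_arr) / np.sqrt(2.0))
    return float(p) if z_arr.ndim == 0 else p


def stouffer_integrate(z_by_contrast, weights) -> float:
    """Weighted Stouffer combination of a vector of Z-scores.

    Missing z values are excluded together with their weights; returns NaN
    when nothing remains.
    """
    z_arr = np.asarray(z_by_contrast, dtype=float)
    w_arr = np.asarray(weights, dtype=float)
    if z_arr.shape != w_arr.shape:
        raise ValueError("z values and weights must align")
    keep = np.isfinite(z_arr)
    if not keep.any():
        return float("nan")
    z_arr, w_arr = z_arr[keep], w_arr[keep]
    return float((w_arr * z_arr).sum() / np.sqrt((w_arr**2).sum()))


def stouffer_integrate_matrix(
    values: pd.DataFrame, weights: pd.Series
) -> pd.Series:
    """Row-wise weighted Stouffer over a rows × contrasts Z matrix."""
    w = weights.reindex(values.columns).to_numpy(dtype=float)
    z = values.to_numpy(dtype=float)
    mask = np.isfinite(z)
    num = np.nansum(np.where(mask, z, 0.0) * w, axis=1)
    denom = np.sqrt(((mask * w) ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    out[~mask.any(axis=1)] = np.nan
    return pd.Series(out, index=values.index, name="Z")


def bh_adjust(p_vector) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` clipped at 1.  NaN entries are
    excluded from the family and propagate as NaN.
    """
    p = np.asarray(p_vector, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[valid] = qv
    return out


def species_presence_filter(m: SignatureMatrix, min_species: int) -> list[str]:
    """Genes observed (non-missing) in contrasts of >= min_species species."""
    n_species = _species_presence(m)
    return list(n_species.index[n_species >= min_species])


def _species_presence(m: SignatureMatrix) -> pd.Series:
    species = m.meta["species"]
    present = m.values.notna()
    by_species = present.T.groupby(species.reindex(present.columns)).any().T
    return by_species.sum(axis=1).rename("n_species")


def classify_conserved_genes(
    results: pd.DataFrame,
    z_hi: float = DEFAULT_Z_HI,
    z_lo: float = DEFAULT_Z_LO,
    sd_cut: float = DEFAULT_SD_CUT,
) -> pd.Series:
    """Band genes by integrated Z and cross-contrast signature SD.

    High-SD bands are evaluated first: |Z| >= z_hi with sd >= sd_cut is the
    strong-but-fluctuating class; |Z| >= z_lo with sd < sd_cut is the
    consistent class; everything else is "none".  A missing SD (gene seen
    in a single contrast) counts as no fluctuation evidence, i.e. low SD.
    """
    z = results["Z"].to_numpy(dtype=float)
    sd = results["sd_sig"].to_numpy(dtype=float)
    sd = np.where(np.isnan(sd), 0.0, sd)

    labels = np.full(len(results), "none", dtype=object)
    labels[(z >= z_hi) & (sd >= sd_cut)] = "up_high_sd"
    labels[(z <= -z_hi) & (sd >= sd_cut)] = "down_high_sd"
    consistent_up = (z >= z_lo) & (sd < sd_cut)
    consistent_down = (z <= -z_lo) & (sd < sd_cut)
    labels[consistent_up] = "up_consistent"
    labels[consistent_down] = "down_consistent"
    return pd.Series(labels, index=results.index, name="class")


def integrate_signature_matrix(
    m: SignatureMatrix,
    weights: pd.Series | None = None,
    min_species: int = DEFAULT_MIN_SPECIES,
    z_hi: float = DEFAULT_Z_HI,
    z_lo: float = DEFAULT_Z_LO,
    sd_cut: float = DEFAULT_SD_CUT,
) -> pd.DataFrame:
    """Full per-gene integration: Z, p, q, signature SD, species count, class.

    Genes failing the >=min_species presence filter are excluded before
    forming the (single) BH family.  SD is computed on the signature scale
    across contrasts where the gene is present (no imputation).
    """
    if weights is None:
        weights = species_balanced_weights(m.meta)
    genes = species_presence_filter(m, min_species)
    if not genes:
        raise ValueError(
            f"no gene is present in at least {min_species} species"
        )
    values = m.values.loc[genes]
    z_values = pd.DataFrame(
        signature_to_z(values.to_numpy()), index=values.index, columns=values.columns
    )
    Z = stouffer_integrate_matrix(z_values, weights)
    p = pd.Series(z_to_p(Z.to_numpy()), index=Z.index, name="p")
    q = pd.Series(bh_adjust(p.to_numpy()), index=Z.index, name="q")
    sd_sig = values.std(axis=1, ddof=1).rename("sd_sig")
    n_species = _species_presence(m).reindex(values.index)

    results = pd.DataFrame(
        {"Z": Z, "p": p, "q": q, "sd_sig": sd_sig, "n_species": n_species}
    )
    results["class"] = classify_conserved_genes(
        results, z_hi=z_hi, z_lo=z_lo, sd_cut=sd_cut
    )
    results.index.name = "gene"
    return results
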