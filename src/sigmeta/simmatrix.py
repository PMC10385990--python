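"""Contrast-by-contrast Pearson correlation of signatures.

Correlations are computed over pairwise-complete genes only; pairs sharing
fewer than ``min_overlap`` genes are suppressed (NaN) rather than reported.
Two-sided p-values use the t-distribution form
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sigmeta.designature import SignatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 100


@dataclass
class CorrelationMatrix:
    """Square contrast correlation matrix with overlap counts and p-values."""

    r: pd.DataFrame
    n_overlap: pd.DataFrame
    p: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (contrast_a, contrast_b, r, n, p) over the upper triangle."""
        cols = self.r.columns
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "contrast_a": a,
                        "contrast_b": b,
                        "r": self.r.at[a, b],
                        "n": self.n_overlap.at[a, b],
                        "p": self.p.at[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_pvalue(r, n_overlap):
    """Two-sided correlation-test p-value (t form, n-2 df).

    Accepts scalars or arrays.  Degenerate |r| = 1 reports p = 0; n < 3
    raises for scalar input and yields NaN element-wise for arrays.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n_overlap, dtype=float)
    scalar = r_arr.ndim == 0
    if scalar and n_arr < 3:
        raise ValueError("correlation p-value requires n >= 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n_arr - 2.0) / (1.0 - r_arr**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n_arr - 2.0, 1.0))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, p)
    p = np.where(n_arr < 3, np.nan, p)
    return float(p) if scalar else p


def pairwise_correlation(
    m: SignatureMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation across all contrast pairs.

    Entries with fewer than ``min_overlap`` shared genes are NaN; a contrast
    with zero variance on an overlap yields a NaN entry with a warning.
    """
    if m.n_contrasts < 2:
        raise ValueError("pairwise correlation requires at least 2 contrasts")

    values = m.values.to_numpy(dtype=float)
    mask = np.isfinite(values)
    x = np.where(mask, values, 0.0)
    mask_f = mask.astype(float)

    # Pairwise-complete sufficient statistics via matrix products.
    n = mask_f.T @ mask_f
    sx = x.T @ mask_f  # sum of column-a values over genes shared with column-b
    sxx = (x**2).T @ mask_f
    sxy = x.T @ x

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx**2 / n
        var_b = var_a.T
        denom = np.sqrt(var_a * var_b)
        r = cov / denom

    degenerate = (denom == 0) & (n > 0)
    if degenerate.any():
        warnings.warn(
            "zero-variance overlap(s) encountered; correlations set to missing",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.where(degenerate, np.nan, r)

    r = np.clip(r, -1.0, 1.0)
    suppressed = n < min_overlap
    r = np.where(suppressed, np.nan, r)
    np.fill_diagonal(r, 1.0)

    p = correlation_pvalue(r, n)
    p = np.where(np.isnan(r), np.nan, p)
    np.fill_diagonal(p, 0.0)

    cols = m.values.columns
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        n_overlap=pd.DataFrame(n.astype(int), index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
    )
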