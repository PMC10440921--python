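"""Shared multiple-testing and p-value combination helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# smallest p a combined statistic is allowed to see; p=0 is clamped here
TINY_P = np.nextafter(0.0, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR). NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def fisher_combine(pvalues) -> float:
    """Fisher's sum-of-logs combined p-value.

    X = -2 * sum(ln p_i) ~ chi-square with 2k degrees of freedom under the
    null; the combined p is its upper tail.  p_i = 0 is clamped to the
    smallest positive float so the log stays finite.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    p = np.sort(np.clip(p, TINY_P, 1.0))  # sorted sum: bitwise permutation-invariant
    x = -2.0 * np.log(p).sum()
    # the tail itself can underflow for extreme inputs; keep it in (0, 1]
    return float(max(stats.chi2.sf(x, 2 * p.size), TINY_P))


def fisher_combine_rows(pmatrix) -> np.ndarray:
    """Row-wise Fisher combination of a genes x comparisons p-value matrix."""
    p = np.sort(np.clip(np.asarray(pmatrix, dtype=float), TINY_P, 1.0), axis=1)
    x = -2.0 * np.log(p).sum(axis=1)
    return np.maximum(stats.chi2.sf(x, 2 * p.shape[1]), TINY_P)
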