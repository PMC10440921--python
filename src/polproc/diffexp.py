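"""Two-condition differential expression with minimal re-implementations of
the two normalization/testing regimes used in the pipeline.

``nb_wald`` targets spike-in-anchored count data: median-of-ratios size
factors, method-of-moments negative-binomial dispersion, and a Wald test on
the log2 fold-change referenced to a t distribution.  ``moderated_t``
targets cohort data: log2-CPM values with an empirical-Bayes (limma-style)
pooled-variance moderated t test.  Neither aims to match any external
package's numerics; both are validated by type-I-error and power
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from ._stats import bh_adjust
from .models import CountMatrix

__all__ = [
    "ComparisonResult",
    "ComparisonSet",
    "size_factors",
    "de_test",
    "call_status",
    "PRESETS",
]

# Workflow presets: the cell-line contrast calls DEGs at fold-change >= 2
# with nominal p <= 0.05; the patient-cohort contrast at FDR < 0.05 with no
# fold-change floor.
PRESETS: dict[str, dict] = {
    "cells_thz531": {"method": "nb_wald", "fc_threshold": 2.0, "p_threshold": 0.05, "use_fdr": False},
    "patients_ega": {"method": "moderated_t", "fc_threshold": 1.0, "p_threshold": 0.05, "use_fdr": True},
}


@dataclass
class ComparisonResult:
    """Per-gene DE statistics for one contrast (treatment vs reference).

    ``table`` is indexed by gene id with columns ``log2fc``, ``p``, ``fdr``
    and (after :func:`call_status`) ``status`` in {up, down, unregulated,
    not_expressed}.
    """

    table: pd.DataFrame
    reference: str
    treatment: str
    method: str = ""
    params: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.treatment}_vs_{self.reference}"

    def degs(self) -> pd.Index:
        if "status" not in self.table.columns:
            raise ValueError("call_status has not been applied")
        return self.table.index[self.table["status"].isin(["up", "down"])]


ComparisonSet = dict[str, ComparisonResult]


def size_factors(counts: CountMatrix, anchor: str = "spike_ins") -> pd.Series:
    """Median-of-ratios sample size factors.

    For each anchor gene with a positive count in every sample, the ratio of
    each sample's count to the gene's geometric mean is formed; the factor
    is the per-sample median of those ratios.  ``anchor='spike_ins'``
    restricts the anchor set to the spike-in controls (constant-expression
    assumption); ``'all_genes'`` uses every gene.
    """
    if anchor == "spike_ins":
        mat = counts.spike_ins()
        if mat.empty:
            raise ValueError("no spike-in genes to anchor normalization")
    elif anchor == "all_genes":
        mat = counts.counts
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    arr = mat.to_numpy(float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no anchor gene has positive counts in every sample")
    logs = np.log(arr[usable])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def _moment_match_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene-wise variances.

    Assumes s^2 ~ s0^2 * F(d, d0) and moment-matches on log s^2 using
    digamma/trigamma identities; d0 = inf (returned as a large cap) when
    the observed spread of log-variances is at or below the sampling
    spread, meaning complete shrinkage to s0^2.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    if z.size < 2:
        return 1e6, float(np.mean(s2)) if s2.size else 1.0
    evar = z.var(ddof=1) - float(special.polygamma(1, d / 2.0))
    if evar <= 1e-8:
        d0 = 1e6
    else:
        f = lambda x: float(special.polygamma(1, x / 2.0)) - evar
        lo, hi = 1e-3, 1e6
        d0 = hi if f(hi) > 0 else (lo if f(lo) < 0 else brentq(f, lo, hi))
    log_s0 = (
        z.mean()
        - float(special.digamma(d / 2.0))
        + np.log(d / 2.0)
        + float(special.digamma(d0 / 2.0))
        - np.log(d0 / 2.0)
    )
    return float(d0), float(np.exp(log_s0))


def de_test(
    counts: CountMatrix,
    reference: str,
    treatment: str,
    method: str = "nb_wald",
    anchor: str | None = None,
    pseudocount: float = 0.5,
) -> ComparisonResult:
    """Two-sided DE test of ``treatment`` vs ``reference``.

    log2fc is the shrinkage-free log2 ratio of normalized condition means
    (with ``pseudocount`` added to each mean to keep zero groups finite);
    ``fdr`` is the Benjamini-Hochberg adjustment over all tested genes.
    Genes with zero counts in both conditions are reported as
    ``not_expressed`` with p = 1 by convention.
    """
    samples_a = counts.samples_for(reference)
    samples_b = counts.samples_for(treatment)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition (got {len(samples_a)} vs {len(samples_b)})"
        )
    bio = counts.biological()
    a = bio[samples_a].to_numpy(float)
    b = bio[samples_b].to_numpy(float)
    all_zero = (a.sum(axis=1) + b.sum(axis=1)) == 0

    # spike-ins are the preferred anchor when present; cohort data without
    # controls falls back to median-of-ratios over all genes, which is
    # robust to compositional shifts that distort plain library scaling
    if anchor is None:
        anchor = "spike_ins" if counts.spike_in_ids else "all_genes"
    sf = size_factors(counts, anchor=anchor)

    if method == "nb_wald":
        log2fc, p = _nb_wald(bio, sf, samples_a, samples_b, pseudocount)
    elif method == "moderated_t":
        log2fc, p = _moderated_t(bio, sf, samples_a, samples_b, pseudocount)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": bh_adjust(p)}, index=bio.index
    )
    table["status"] = np.where(all_zero, "not_expressed", "untested")
    return ComparisonResult(
        table, reference, treatment, method, {"anchor": anchor, "pseudocount": pseudocount}
    )


def _nb_wald(bio, sf, samples_a, samples_b, pseudocount):
    qa = bio[samples_a].to_numpy(float) / sf[samples_a].to_numpy()
    qb = bio[samples_b].to_numpy(float) / sf[samples_b].to_numpy()
    na, nb = qa.shape[1], qb.shape[1]
    mean_a, mean_b = qa.mean(axis=1), qb.mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    # method-of-moments NB dispersion pooled across the two groups:
    # Var(q) = q_bar * mean(1/sf) + alpha * q_bar^2 on the normalized scale
    inv_sf_a = float(np.mean(1.0 / sf[samples_a].to_numpy()))
    inv_sf_b = float(np.mean(1.0 / sf[samples_b].to_numpy()))
    var_a = qa.var(axis=1, ddof=1)
    var_b = qb.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mean_a * inv_sf_a) / mean_a**2
        alpha_b = (var_b - mean_b * inv_sf_b) / mean_b**2
    wa, wb = na - 1, nb - 1
    alpha = np.nanmax(
        [np.zeros_like(mean_a), (wa * alpha_a + wb * alpha_b) / (wa + wb)], axis=0
    )
    var_mean_a = (mean_a * inv_sf_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b * inv_sf_b + alpha * mean_b**2) / nb
    se2 = (
        var_mean_a / (mean_a + pseudocount) ** 2 + var_mean_b / (mean_b + pseudocount) ** 2
    ) / np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / np.sqrt(se2)
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(p), p, 1.0)
    return log2fc, p


def _moderated_t(bio, sf, samples_a, samples_b, pseudocount):
    norm = bio / sf
    logq = np.log2(norm + pseudocount)
    ya = logq[samples_a].to_numpy(float)
    yb = logq[samples_b].to_numpy(float)
    na, nb = ya.shape[1], yb.shape[1]
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    diff = mean_b - mean_a
    d = na + nb - 2
    pooled = (ya.var(axis=1, ddof=1) * (na - 1) + yb.var(axis=1, ddof=1) * (nb - 1)) / d
    d0, s0 = _moment_match_prior(pooled, d)
    s2_post = (d0 * s0 + d * pooled) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    df_total = min(d + d0, 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(p), p, 1.0)
    return diff, p


def call_status(
    result: ComparisonResult,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> ComparisonResult:
    """Regulation calls: up iff 2^log2fc >= fc_threshold and the p (or FDR)
    criterion is met; down symmetric; otherwise unregulated.  Genes already
    flagged ``not_expressed`` keep that status.
    """
    t = result.table
    crit = t["fdr"] < p_threshold if use_fdr else t["p"] <= p_threshold
    log_thr = np.log2(fc_threshold)
    status = np.where(
        (t["log2fc"] >= log_thr) & crit,
        "up",
        np.where((t["log2fc"] <= -log_thr) & crit, "down", "unregulated"),
    )
    status = np.where(t["status"] == "not_expressed", "not_expressed", status)
    table = t.copy()
    table["status"] = status
    params = dict(result.params)
    params.update(fc_threshold=fc_threshold, p_threshold=p_threshold, use_fdr=use_fdr)
    return ComparisonResult(table, result.reference, result.treatment, result.method, params)
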