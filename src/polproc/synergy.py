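"""Median-effect dose-response fitting and Chou-Talalay combination index.

The median-effect equation fa/fu = (D/Dm)^m linearizes to
log(fa/(1-fa)) = m log D - m log Dm, fitted by ordinary least squares.
For a combination point (D1, D2) producing effect fa, the combination
index is CI = D1/Dx1 + D2/Dx2 with Dx_i = Dm_i (fa/(1-fa))^(1/m_i), the
single-agent dose of drug i that alone yields fa.  CI < 1 reads synergism,
CI = 1 additivity (Loewe), CI > 1 antagonism.  The two-term
(mutually-exclusive) form is the default, matching the usual convention
for a fixed-dose sensitizer plus a varying partner drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
__all__ = [
    "DoseResponseCurve",
    "CIResult",
    "fit_median_effect",
    "combination_index",
    "fa_from_viability",
]

FA_EPSILON = 0.005       # fa clamped to (eps, 1-eps) before the logit transform
ADDITIVE_BAND = (0.95, 1.05)


@dataclass
class DoseResponseCurve:
    """Fitted median-effect parameters for one drug."""

    doses: np.ndarray
    fa: np.ndarray
    m: float                 # Hill slope
    dm: float                # median-effect dose (same units as doses)
    r_squared: float
    n_used: int
    excluded: int = 0

    def dose_for(self, fa: float) -> float:
        """Single-agent dose producing fraction affected ``fa``."""
        return float(self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m))

    def fa_at(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(dose > 0, 1.0 / (1.0 + (self.dm / dose) ** self.m), 0.0)


@dataclass
class CIResult:
    """Combination-index values over a set of combination points."""

    points: pd.DataFrame     # dose1, dose2, fa, dx1, dx2, ci, verdict
    mean_ci: float
    drug1: str = ""
    drug2: str = ""
    additive_band: tuple[float, float] = ADDITIVE_BAND
    extras: dict = field(default_factory=dict)


def fa_from_viability(viability, epsilon: float = FA_EPSILON) -> np.ndarray:
    """Fraction affected = 1 - relative viability, clamped into
    (epsilon, 1 - epsilon) so the logit stays finite under noise."""
    fa = 1.0 - np.asarray(viability, dtype=float)
    return np.clip(fa, epsilon, 1.0 - epsilon)


def fit_median_effect(
    doses,
    fa,
    epsilon: float = FA_EPSILON,
    min_points: int = 3,
    weighting: str = "delta",
) -> DoseResponseCurve:
    """Least-squares fit of the linearized median-effect equation.

    By default the regression is weighted by (1 - fa)^2, the delta-method
    variance weighting for multiplicative error on the fraction affected:
    the logit amplifies noise near fa = 1, and unweighted OLS lets those
    points dominate the slope.  ``weighting='none'`` gives the plain OLS
    fit; on noise-free data both are exact and identical.

    Points with fa outside (epsilon, 1 - epsilon) carry no information
    after clamping and are excluded with a warning; fewer than
    ``min_points`` usable points is an error.  A warning is emitted when
    r-squared < 0.5 (grossly non-monotone data).
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have equal length")
    usable = (doses > 0) & (fa > epsilon) & (fa < 1.0 - epsilon)
    n_excl = int((~usable).sum())
    if n_excl:
        warnings.warn(
            f"{n_excl} dose point(s) outside the usable effect range excluded",
            stacklevel=2,
        )
    if usable.sum() < min_points:
        raise ValueError(
            f"only {int(usable.sum())} usable dose points; need >= {min_points}"
        )
    x = np.log10(doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    if weighting == "delta":
        w = (1.0 - fa[usable]) ** 2
    elif weighting == "none":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    wsum = w.sum()
    xb, yb = (w * x).sum() / wsum, (w * y).sum() / wsum
    sxx = (w * (x - xb) ** 2).sum()
    if sxx <= 0:
        raise ValueError("all usable doses identical; cannot fit a slope")
    m = float((w * (x - xb) * (y - yb)).sum() / sxx)
    if m <= 0:
        raise ValueError("non-positive fitted Hill slope; dose-response is inverted")
    intercept = yb - m * xb
    dm = float(10.0 ** (-intercept / m))
    resid = y - (m * x + intercept)
    ss_tot = (w * (y - yb) ** 2).sum()
    r2 = float(1.0 - (w * resid**2).sum() / ss_tot) if ss_tot > 0 else 1.0
    if r2 < 0.5:
        warnings.warn(f"median-effect fit r^2 = {r2:.3f} < 0.5", stacklevel=2)
    return DoseResponseCurve(doses[usable], fa[usable], m, dm, r2, int(usable.sum()), n_excl)


def _verdict(ci: float, band: tuple[float, float]) -> str:
    if ci < band[0]:
        return "synergism"
    if ci > band[1]:
        return "antagonism"
    return "additive"


def combination_index(
    curve1: DoseResponseCurve,
    curve2: DoseResponseCurve,
    combo_points: pd.DataFrame,
    epsilon: float = FA_EPSILON,
    drug1: str = "drug1",
    drug2: str = "drug2",
    additive_band: tuple[float, float] = ADDITIVE_BAND,
) -> CIResult:
    """Two-term combination index at each observed combination point.

    ``combo_points`` needs columns ``dose1``, ``dose2`` and either ``fa``
    or ``viability``.  Points whose fa falls outside (epsilon, 1-epsilon)
    are skipped with a warning; a zero dose contributes nothing to its CI
    term (single-agent limit).
    """
    pts = combo_points.copy()
    if "fa" not in pts.columns:
        if "viability" not in pts.columns:
            raise ValueError("combo_points needs an 'fa' or 'viability' column")
        pts["fa"] = 1.0 - pts["viability"].astype(float)
    keep = (pts["fa"] > epsilon) & (pts["fa"] < 1.0 - epsilon)
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} combination point(s) outside the usable "
            "effect range skipped",
            stacklevel=2,
        )
    pts = pts.loc[keep].reset_index(drop=True)
    if pts.empty:
        raise ValueError("no usable combination points")
    rows = []
    for _, row in pts.iterrows():
        fa = float(row["fa"])
        dx1 = curve1.dose_for(fa)
        dx2 = curve2.dose_for(fa)
        ci = 0.0
        if row["dose1"] > 0:
            ci += float(row["dose1"]) / dx1
        if row["dose2"] > 0:
            ci += float(row["dose2"]) / dx2
        rows.append((float(row["dose1"]), float(row["dose2"]), fa, dx1, dx2, ci))
    out = pd.DataFrame(rows, columns=["dose1", "dose2", "fa", "dx1", "dx2", "ci"])
    out["verdict"] = [_verdict(c, additive_band) for c in out["ci"]]
    return CIResult(out, float(out["ci"].mean()), drug1, drug2, additive_band)
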