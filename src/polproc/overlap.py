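"""Gene-set overlaps with hypergeometric significance and GMT-based
over-representation analysis.

The upper-tail convention is P[X >= k] (the standard enrichment reading of
``phyper(k - 1, ..., lower.tail = FALSE)``).  The universe is always
supplied explicitly: overlap p-values depend entirely on it, and a silently
inferred universe would fabricate significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust

__all__ = ["OverlapResult", "overlap_test", "ora"]


@dataclass
class OverlapResult:
    universe_size: int
    n1: int
    n2: int
    overlap: int
    p_upper: float              # P[X >= k]; floored at the smallest positive float
    fold_enrichment: float      # k * N / (n1 * n2)
    log10_p: float = 0.0        # exact log-space tail, usable beyond float underflow

    def as_dict(self) -> dict:
        return {
            "N": self.universe_size,
            "n1": self.n1,
            "n2": self.n2,
            "k": self.overlap,
            "p_upper": self.p_upper,
            "log10_p": self.log10_p,
            "fold_enrichment": self.fold_enrichment,
        }


def _check_subset(name: str, s: set, universe: set) -> None:
    stray = s - universe
    if stray:
        raise ValueError(f"{name} contains ids outside the universe: {sorted(stray)[:10]}")


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric upper-tail test of the overlap between two gene sets.

    p = P[X >= k] where X is the overlap of random draws of sizes |a| and
    |b| from the universe.  Symmetric in its two sets by construction.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    _check_subset("set_a", a, universe)
    _check_subset("set_b", b, universe)
    n = len(universe)
    k = len(a & b)
    # order (n1, n2) canonically: the hypergeometric tail is mathematically
    # symmetric and ordering makes it bitwise symmetric too
    n1, n2 = sorted((len(a), len(b)))
    if k == 0:
        p, log10_p = 1.0, 0.0
    else:
        p = float(stats.hypergeom.sf(k - 1, n, n1, n2))
        logs = stats.hypergeom.logpmf(np.arange(k, min(n1, n2) + 1), n, n1, n2)
        logs = logs[np.isfinite(logs)]
        log10_p = float(special.logsumexp(logs) / np.log(10.0)) if logs.size else -np.inf
        if p <= 0.0 or p < 1e-280:  # linear scale underflows; use the log tail
            p = float(max(np.exp(log10_p * np.log(10.0)), np.nextafter(0.0, 1.0)))
    fold = k * n / (n1 * n2) if n1 and n2 else float("nan")
    return OverlapResult(n, len(a), len(b), k, min(p, 1.0), fold, min(log10_p, 0.0))


def ora(query, collection: dict[str, set[str]], universe) -> pd.DataFrame:
    """Over-representation of a query gene list against a GMT collection.

    One hypergeometric overlap test per collection set, BH-adjusted across
    the collection; rows sorted by raw p.  Collection members outside the
    universe are ignored (the universe defines what could have been drawn).
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    universe = set(universe)
    _check_subset("query", query, universe)
    rows = []
    for name, members in collection.items():
        inside = set(members) & universe
        if not inside:
            continue
        r = overlap_test(query, inside, universe)
        rows.append((name, r.universe_size, len(query), len(inside), r.overlap, r.fold_enrichment, r.p_upper))
    if not rows:
        raise ValueError("no collection set intersects the universe")
    df = pd.DataFrame(
        rows, columns=["set", "N", "n_query", "n_set", "overlap", "fold_enrichment", "p"]
    ).set_index("set")
    df["fdr"] = bh_adjust(df["p"])
    return df.sort_values("p")
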