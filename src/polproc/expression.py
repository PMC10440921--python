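"""FPKM/CPM quantification and the intergenic-background expression filter.

A gene counts as expressed in a condition when its mean FPKM over the
condition's replicates exceeds the 98th percentile of the FPKM-equivalents
of intergenic segments (the genomic background).  Only genes expressed in
at least one of the two compared conditions enter differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import CountMatrix, CoverageTrack, GenomeAnnotation

__all__ = [
    "ExpressionTable",
    "BackgroundModel",
    "compute_fpkm",
    "coverage_fpkm",
    "background_threshold",
    "filter_expressed",
]


@dataclass
class ExpressionTable:
    """FPKM and CPM matrices over biological genes plus sample conditions."""

    fpkm: pd.DataFrame
    cpm: pd.DataFrame
    conditions: pd.Series  # sample -> condition

    def condition_mean_fpkm(self, condition: str) -> pd.Series:
        cols = self.conditions.index[self.conditions == condition]
        if len(cols) == 0:
            raise KeyError(f"no samples for condition {condition!r}")
        return self.fpkm[list(cols)].mean(axis=1)


@dataclass
class BackgroundModel:
    """Intergenic background FPKM distribution and its 98th-percentile cut."""

    intergenic_fpkm: np.ndarray
    threshold: float
    quantile: float = 98.0


def compute_fpkm(
    counts: CountMatrix,
    annotation: GenomeAnnotation,
    include_spike_ins_in_library: bool = False,
) -> ExpressionTable:
    """FPKM and CPM from raw counts.

    FPKM = count * 1e9 / (library_size * gene_length); CPM = count * 1e6 /
    library_size.  Spike-in control rows are excluded from both the output
    and (by default) the library size, so CPM columns over biological genes
    sum to exactly 1e6.
    """
    bio = counts.biological()
    library = (counts.counts if include_spike_ins_in_library else bio).sum(axis=0)
    if (library == 0).any():
        bad = list(library.index[library == 0])
        raise ValueError(f"zero library size for samples {bad}")
    lengths = annotation.gene_lengths().reindex(bio.index)
    if lengths.isna().any():
        missing = list(bio.index[lengths.isna()])[:5]
        raise ValueError(f"genes missing from annotation: {missing}")
    fpkm = bio * 1e9 / library
    fpkm = fpkm.div(lengths.astype(float), axis=0)
    cpm = bio * 1e6 / library
    conditions = counts.sample_meta.loc[list(bio.columns), "condition"].astype(str)
    return ExpressionTable(fpkm, cpm, conditions)


def coverage_fpkm(track: CoverageTrack, regions) -> np.ndarray:
    """FPKM-equivalents of genomic regions from per-base coverage.

    Depth is treated as single-base read units, so the region's fragment
    count is its summed depth:  FPKM_eq = sum(depth) * 1e9 /
    (total_mapped_reads * region_length) = mean_depth * 1e9 / total.
    ``regions`` is an iterable of (chrom, start, end).
    """
    out = []
    for chrom, start, end in regions:
        seg = track.depth[chrom][start:end]
        if seg.size == 0:
            raise ValueError(f"empty region {chrom}:{start}-{end}")
        out.append(float(seg.mean()) * 1e9 / track.total_mapped_reads)
    return np.asarray(out)


def background_threshold(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    quantile: float = 98.0,
    min_segment_length: int = 200,
) -> BackgroundModel:
    """Background cut = the ``quantile`` (default 98th) percentile of
    intergenic-segment FPKM-equivalents, with linear interpolation between
    order statistics.
    """
    segments = annotation.intergenic_segments(min_length=min_segment_length)
    if not segments:
        raise ValueError("no intergenic segments; annotation leaves no background")
    values = coverage_fpkm(track, segments)
    threshold = float(np.percentile(values, quantile, method="linear"))
    return BackgroundModel(values, threshold, quantile)


def filter_expressed(
    expr: ExpressionTable,
    background: BackgroundModel | float,
    comparison: tuple[str, str],
) -> pd.DataFrame:
    """Expression calls for a two-condition comparison.

    Returns a frame indexed by gene with per-condition mean FPKM, a
    per-condition boolean (mean FPKM strictly greater than the background
    threshold) and ``expressed`` = true in at least one of the two
    conditions.  Genes at exactly the threshold are excluded.
    """
    threshold = background.threshold if isinstance(background, BackgroundModel) else float(background)
    cond_a, cond_b = comparison
    mean_a = expr.condition_mean_fpkm(cond_a)
    mean_b = expr.condition_mean_fpkm(cond_b)
    out = pd.DataFrame(
        {
            f"fpkm.{cond_a}": mean_a,
            f"fpkm.{cond_b}": mean_b,
            f"expressed.{cond_a}": mean_a > threshold,
            f"expressed.{cond_b}": mean_b > threshold,
        }
    )
    out["expressed"] = out[f"expressed.{cond_a}"] | out[f"expressed.{cond_b}"]
    return out
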