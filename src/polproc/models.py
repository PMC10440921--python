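"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 0-based, half-open ``[start, end)``.  File
readers convert at the boundary (GTF is 1-based inclusive on disk), so no
other module ever reasons about coordinate dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "CoverageTrack",
    "CountMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a transcription unit from TSS to TES.

    ``start``/``end`` are 0-based half-open on the chromosome; the TSS is
    ``start`` for plus-strand genes and ``end - 1`` for minus-strand genes.
    ``exons`` are half-open intervals sorted in genomic order and contained
    in ``[start, end)``; a gene with no annotated exon structure carries a
    single exon spanning the whole body.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(self.exons) or ((self.start, self.end),)
        object.__setattr__(self, "exons", exons)
        prev_end = self.start
        for s, e in exons:
            if s >= e:
                raise ValidationError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < prev_end and (s, e) != exons[0]:
                raise ValidationError(f"gene {self.gene_id}: exons overlap or unsorted")
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene body")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """A set of gene models plus the chromosome sizes that frame them."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValidationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > size:
                raise ValidationError(
                    f"gene {g.gene_id}: end {g.end} beyond {g.chrom} size {size}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def subset(self, gene_ids) -> "GenomeAnnotation":
        wanted = set(gene_ids)
        return GenomeAnnotation(
            [g for g in self.genes if g.gene_id in wanted], dict(self.chrom_sizes)
        )

    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes}, name="length")

    def intergenic_segments(self, min_length: int = 1) -> list[tuple[str, int, int]]:
        """Complement of gene spans per chromosome, split at genes.

        Segments shorter than ``min_length`` are dropped.
        """
        by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chrom_sizes}
        for g in self.genes:
            by_chrom[g.chrom].append((g.start, g.end))
        segments = []
        for chrom, size in self.chrom_sizes.items():
            cursor = 0
            for s, e in sorted(by_chrom[chrom]):
                if s > cursor and s - cursor >= min_length:
                    segments.append((chrom, cursor, s))
                cursor = max(cursor, e)
            if size - cursor >= min_length:
                segments.append((chrom, cursor, size))
        return segments


@dataclass
class CoverageTrack:
    """Dense per-base sequencing depth plus the library's mapped-read count.

    ``total_mapped_reads`` is carried explicitly (sidecar value) because
    per-million scaling refers to the library, which the coverage arrays
    alone cannot recover.
    """

    depth: dict[str, np.ndarray]
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValidationError("total_mapped_reads must be positive")
        for chrom, arr in self.depth.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValidationError(f"negative depth on {chrom}")
            self.depth[chrom] = arr

    def gene_depth(self, gene: GeneModel) -> np.ndarray:
        """Per-base depth over the gene body, oriented TSS -> TES."""
        arr = self.depth[gene.chrom][gene.start : gene.end]
        return arr[::-1] if gene.strand == "-" else arr

    def cpm_scale(self) -> float:
        return 1e6 / self.total_mapped_reads


@dataclass
class CountMatrix:
    """Gene-by-sample raw counts with sample metadata and spike-in flags.

    ``sample_meta`` is indexed by sample id and must provide a ``condition``
    column; an optional ``group`` column carries higher-level labels (e.g.
    tumor / fetal / adult).  ``spike_in_ids`` marks exogenous control genes
    assumed constant in expectation across conditions.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    spike_in_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if "condition" not in self.sample_meta.columns:
            raise ValidationError("sample_meta must have a 'condition' column")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        self.spike_in_ids = frozenset(self.spike_in_ids)
        stray = self.spike_in_ids - set(self.counts.index)
        if stray:
            raise ValidationError(f"spike-in ids not in matrix: {sorted(stray)[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def condition_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "condition"])

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["condition"] == condition])

    def biological(self) -> pd.DataFrame:
        """Counts with spike-in rows removed."""
        return self.counts.drop(index=list(self.spike_in_ids), errors="ignore")

    def spike_ins(self) -> pd.DataFrame:
        return self.counts.loc[sorted(self.spike_in_ids)]
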