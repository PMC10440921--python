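"""Readers and writers for the standard formats the pipeline touches.

GTF (1-based inclusive) and BED12 (0-based half-open) are both converted to
the internal 0-based half-open convention on read.  Every reader has a
writer counterpart that is its exact inverse on valid files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from .models import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    ValidationError,
)

__all__ = [
    "read_gene_models",
    "write_gene_models",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts",
    "write_counts",
    "read_gene_sets",
    "write_gene_sets",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "ParseError",
]


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line."""


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path, chrom_sizes=None, dialect: str | None = None) -> GenomeAnnotation:
    """Read gene models from GTF or BED12 into a :class:`GenomeAnnotation`.

    The dialect is auto-detected from the extension (``.gtf`` / ``.gff`` vs
    ``.bed``) unless given explicitly.  When ``chrom_sizes`` is omitted it is
    taken as the rightmost gene end per chromosome.
    """
    path = Path(path)
    if dialect is None:
        dialect = "bed12" if path.suffix.lower() == ".bed" else "gtf"
    if dialect == "gtf":
        genes = _read_gtf(path)
    elif dialect == "bed12":
        genes = _read_bed12(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes, dict(chrom_sizes))


def _read_gtf(path: Path) -> list[GeneModel]:
    # pyranges handles the 1-based -> 0-based conversion and attribute parsing
    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # pragma: no cover - exact error text varies
        raise ParseError(f"{path}: not parseable as GTF ({exc})") from exc
    if df.empty or "gene_id" not in df.columns:
        raise ParseError(f"{path}: no gene_id-bearing records found")
    genes: list[GeneModel] = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        gene_rows = sub[sub["Feature"] == "gene"]
        exon_rows = sub[sub["Feature"] == "exon"]
        if len(gene_rows):
            row = gene_rows.iloc[0]
            start, end = int(row["Start"]), int(row["End"])
            chrom, strand = str(row["Chromosome"]), str(row["Strand"])
        elif len(exon_rows):
            start = int(exon_rows["Start"].min())
            end = int(exon_rows["End"].max())
            chrom = str(exon_rows.iloc[0]["Chromosome"])
            strand = str(exon_rows.iloc[0]["Strand"])
        else:
            continue
        if end <= start:
            raise ValidationError(f"gene {gene_id}: end {end} <= start {start}")
        exons = tuple(
            sorted((int(r["Start"]), int(r["End"])) for _, r in exon_rows.iterrows())
        )
        genes.append(GeneModel(str(gene_id), chrom, start, end, strand, exons))
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def write_gene_models(annotation: GenomeAnnotation, path, dialect: str | None = None) -> None:
    """Write gene models as GTF (gene + exon records) or BED12."""
    path = Path(path)
    if dialect is None:
        dialect = "bed12" if path.suffix.lower() == ".bed" else "gtf"
    with open(path, "w") as fh:
        for g in annotation.genes:
            if dialect == "gtf":
                attr = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tpolproc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attr}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tpolproc\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr}\n"
                    )
            elif dialect == "bed12":
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, e in g.exons)
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# coverage


def read_bedgraph(path, chrom_sizes: dict[str, int], total_mapped_reads: int) -> CoverageTrack:
    """Read a bedGraph file into a dense per-base :class:`CoverageTrack`.

    Bases not covered by any record are 0.  Overlapping records are a
    format violation and raise :class:`ValidationError`.
    """
    depth = {c: np.zeros(size, dtype=float) for c, size in chrom_sizes.items()}
    covered_to: dict[str, int] = {}
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    for chrom, start, end, value in sorted(records):
        if chrom not in depth:
            raise ValidationError(f"unknown chromosome {chrom!r} in bedGraph")
        if end > chrom_sizes[chrom]:
            raise ValidationError(
                f"interval {chrom}:{start}-{end} exceeds chromosome size {chrom_sizes[chrom]}"
            )
        if start < covered_to.get(chrom, 0):
            raise ValidationError(f"overlapping bedGraph records at {chrom}:{start}")
        depth[chrom][start:end] = value
        covered_to[chrom] = end
    return CoverageTrack(depth, total_mapped_reads)


def write_bedgraph(track: CoverageTrack, path, include_zero: bool = False) -> None:
    """Write a coverage track as bedGraph (runs of equal value collapsed)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0 and not include_zero:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# counts, gene sets, sidecars


def read_counts(path, meta_path=None, spike_in_prefix: str = "ERCC-") -> CountMatrix:
    """Read a genes-in-rows TSV count matrix.

    Sample metadata is read from ``meta_path`` (TSV: sample, condition,
    [group]); when omitted, each sample is its own condition.  Rows whose id
    starts with ``spike_in_prefix`` are flagged as spike-in controls.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    as_float = df.astype(float)
    if not np.allclose(as_float, np.round(as_float)) or (as_float < 0).any().any():
        raise ValidationError(f"{path}: counts must be non-negative integers")
    counts = as_float.round().astype(np.int64)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame({"condition": list(counts.columns)}, index=counts.columns)
    spikes = frozenset(g for g in counts.index if str(g).startswith(spike_in_prefix))
    return CountMatrix(counts, meta, spikes)


def write_counts(matrix: CountMatrix, path, meta_path=None) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs name, description, >=1 member")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
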