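import numpy as np
import pandas as pd
import pytest

from polproc.models import CountMatrix, CoverageTrack, GeneModel, GenomeAnnotation


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Three genes on two chromosomes, both strands, with intergenic gaps."""
    genes = [
        GeneModel("gA", "chr1", 1000, 6000, "+"),
        GeneModel("gB", "chr1", 10000, 14000, "-"),
        GeneModel("gC", "chr2", 2000, 7000, "+"),
    ]
    return GenomeAnnotation(genes, {"chr1": 20000, "chr2": 10000})


def make_track(annotation: GenomeAnnotation, fill=0.0, total_mapped_reads=1_000_000):
    depth = {c: np.full(size, float(fill)) for c, size in annotation.chrom_sizes.items()}
    return CoverageTrack(depth, total_mapped_reads)


def decay_track(annotation, lam, baseline=100.0, total_mapped_reads=1_000_000):
    """Noise-free exponential-decay coverage over every gene body."""
    track = make_track(annotation, 0.0, total_mapped_reads)
    for g in annotation.genes:
        x = (np.arange(g.length) + 0.5) / g.length
        mu = baseline * np.exp(-lam * x)
        track.depth[g.chrom][g.start : g.end] = mu[::-1] if g.strand == "-" else mu
    return track


@pytest.fixture
def toy_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 40, 100],
            "s2": [12, 0, 38, 110],
            "s3": [50, 0, 42, 105],
            "s4": [55, 0, 41, 95],
        },
        index=pd.Index(["g1", "g2", "g3", "ERCC-0001"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {"condition": ["ctrl", "ctrl", "trt", "trt"]}, index=counts.columns
    )
    return CountMatrix(counts, meta, frozenset(["ERCC-0001"]))
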