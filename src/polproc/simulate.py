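"""Synthetic data with planted ground truth.

The generators emulate the statistical structure of a CDK12/13-inhibition
study design: multi-condition bulk RNA-seq counts with spike-in controls
and a planted four-cluster co-regulation pattern across three sample groups
(tumor / fetal-like / adult-like), per-gene coverage tracks whose 5'->3'
decay is governed by a single processivity parameter, intergenic background
signal, and Hill-model dose-response curves with a known interaction mode.

Processivity model
------------------
Expected depth at fractional position ``x`` in [0, 1] along the gene body
(TSS at x=0) is ``baseline * exp(-lam * x)``.  ``lam = 0`` gives uniform
coverage (a fully processive polymerase); large ``lam`` collapses the
signal onto the 5' end.  The distal/proximal depth ratio over windows
[a, a+w] and [b, b+w] has the closed form ``exp(-lam * (b - a))``, which
downstream stages are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import CountMatrix, CoverageTrack, GenomeAnnotation, GeneModel

__all__ = [
    "SyntheticTruth",
    "simulate_annotation",
    "plant_expression_truth",
    "plant_processivity_truth",
    "plant_drug_truth",
    "simulate_coverage",
    "simulate_counts",
    "simulate_dose_response",
    "hill_fraction_affected",
    "loewe_fraction_affected",
    "CLUSTER_SHAPES",
]

# Standardized group-mean shapes (tumor, fetal, adult) for the four planted
# co-regulation clusters.  Each shape is differentially expressed with the
# same sign in both tumor-vs-fetal and tumor-vs-adult contrasts (a common
# DEG), yet all four directions remain distinct after per-gene
# standardization, so k-means can tell them apart.
CLUSTER_SHAPES: dict[int, tuple[float, float, float]] = {
    1: (1.0, -0.5, -0.5),   # tumor-specific up
    2: (1.0, 0.0, -1.0),    # up in tumor and fetal relative to adult
    3: (-1.0, 0.5, 0.5),    # tumor-specific down
    4: (-1.0, 0.0, 1.0),    # down in tumor and fetal relative to adult
}


@dataclass
class SyntheticTruth:
    """Planted ground truth, losslessly serializable to JSON.

    ``genes`` is indexed by gene id with columns:

    - ``is_expressed``: whether the gene carries real signal;
    - ``cluster``: planted co-regulation cluster (1..4) or 0 for none;
    - ``baseline``: expected count at the reference condition;
    - ``effect.<condition>``: planted log2 shift of that condition;
    - ``lambda.<condition>``: processivity decay rate for coverage tracks;
    - ``coverage_baseline``: expected per-base depth at the TSS.

    ``depth_multipliers`` are the per-sample library-size factors the count
    generator applied (the quantity size-factor estimation must recover).
    """

    genes: pd.DataFrame
    conditions: list[str] = field(default_factory=list)
    depth_multipliers: dict[str, float] = field(default_factory=dict)
    drugs: dict[str, dict] = field(default_factory=dict)
    combos: dict[str, dict] = field(default_factory=dict)

    def effect(self, condition: str) -> pd.Series:
        col = f"effect.{condition}"
        if col not in self.genes.columns:
            return pd.Series(0.0, index=self.genes.index)
        return self.genes[col]

    def log2fc(self, reference: str, treatment: str) -> pd.Series:
        """Planted log2 fold-change of ``treatment`` over ``reference``."""
        return (self.effect(treatment) - self.effect(reference)).rename("log2fc")

    def decay(self, condition: str) -> pd.Series:
        col = f"lambda.{condition}"
        if col not in self.genes.columns:
            raise KeyError(f"no processivity truth for condition {condition!r}")
        return self.genes[col]

    def to_dict(self) -> dict:
        return {
            "genes": {
                "index": list(self.genes.index),
                "columns": list(self.genes.columns),
                "data": self.genes.to_numpy().tolist(),
            },
            "conditions": self.conditions,
            "depth_multipliers": self.depth_multipliers,
            "drugs": self.drugs,
            "combos": self.combos,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        genes = pd.DataFrame(
            d["genes"]["data"],
            index=pd.Index(d["genes"]["index"], name="gene_id"),
            columns=d["genes"]["columns"],
        )
        if "is_expressed" in genes.columns:
            genes["is_expressed"] = genes["is_expressed"].astype(bool)
        if "cluster" in genes.columns:
            genes["cluster"] = genes["cluster"].astype(int)
        return cls(
            genes,
            list(d.get("conditions", [])),
            dict(d.get("depth_multipliers", {})),
            {k: dict(v) for k, v in d.get("drugs", {}).items()},
            {k: dict(v) for k, v in d.get("combos", {}).items()},
        )


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    n_genes: int,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    length_meanlog: float = 8.6,
    length_sdlog: float = 0.5,
    min_length: int = 500,
) -> GenomeAnnotation:
    """Place non-overlapping genes with log-normal lengths and random strand.

    Raises if the requested footprint exceeds 70% of the genome (intergenic
    space must remain for background estimation) or if placement fails
    after bounded retries.
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
    rng = np.random.default_rng(seed)
    genome = sum(chrom_sizes.values())
    lengths = np.maximum(
        min_length, rng.lognormal(length_meanlog, length_sdlog, size=n_genes)
    ).astype(int)
    if lengths.sum() > 0.7 * genome:
        raise ValueError(
            f"gene footprint {lengths.sum()} bp exceeds 70% of genome {genome} bp; "
            "use a larger genome or fewer/shorter genes"
        )
    # place longest-first into the free-interval list: each gene picks a
    # gap that fits, with probability proportional to the number of valid
    # start positions, so placement succeeds whenever the footprint fits
    free: list[tuple[str, int, int]] = [(c, 0, chrom_sizes[c]) for c in sorted(chrom_sizes)]
    genes: list[GeneModel] = []
    for i in np.argsort(lengths)[::-1]:
        length = int(lengths[i])
        slots = np.array(
            [max(0, (e - s) - length + 1) for _, s, e in free], dtype=float
        )
        if slots.sum() == 0:
            raise RuntimeError(
                f"could not place gene of length {length} without overlap; "
                "try a larger genome"
            )
        gi = int(rng.choice(len(free), p=slots / slots.sum()))
        chrom, s, e = free.pop(gi)
        start = s + int(rng.integers(0, (e - s) - length + 1))
        end = start + length
        if start > s:
            free.append((chrom, s, start))
        if end < e:
            free.append((chrom, end, e))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:05d}", chrom, start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GenomeAnnotation(genes, dict(chrom_sizes))


# ---------------------------------------------------------------------------
# planted truth


def plant_expression_truth(
    annotation: GenomeAnnotation,
    groups: tuple[str, str, str] = ("tumor", "fetal", "adult"),
    n_per_cluster: int = 25,
    frac_silent: float = 0.1,
    amplitude: float = 3.0,
    baseline_meanlog: float = 5.5,
    baseline_sdlog: float = 1.0,
    silent_baseline: float = 0.02,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant the three-group, four-cluster co-regulation structure.

    ``amplitude`` scales the cluster shapes (log2 units): a cluster-1 gene
    has a planted log2FC of ``1.5 * amplitude`` in tumor vs fetal or adult.
    The remaining genes are nulls (all effects zero) except a ``frac_silent``
    fraction planted as not expressed (near-zero baseline).
    """
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in annotation.genes]
    n = len(ids)
    if 4 * n_per_cluster > n:
        raise ValueError("not enough genes for 4 clusters of the requested size")
    order = rng.permutation(n)
    cluster = np.zeros(n, dtype=int)
    for c in range(1, 5):
        cluster[order[(c - 1) * n_per_cluster : c * n_per_cluster]] = c
    remaining = order[4 * n_per_cluster :]
    n_silent = int(round(frac_silent * n))
    silent_idx = remaining[:n_silent]
    is_expressed = np.ones(n, dtype=bool)
    is_expressed[silent_idx] = False
    baseline = rng.lognormal(baseline_meanlog, baseline_sdlog, size=n)
    baseline[~is_expressed] = silent_baseline
    genes = pd.DataFrame(
        {"is_expressed": is_expressed, "cluster": cluster, "baseline": baseline},
        index=pd.Index(ids, name="gene_id"),
    )
    for gi, grp in enumerate(groups):
        eff = np.zeros(n)
        for c, shape in CLUSTER_SHAPES.items():
            eff[cluster == c] = amplitude * shape[gi]
        genes[f"effect.{grp}"] = eff
    return SyntheticTruth(genes, conditions=list(groups))


def plant_processivity_truth(
    annotation: GenomeAnnotation,
    lambdas: dict[str, float | np.ndarray],
    coverage_baseline: float = 100.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant per-condition processivity decay rates on every gene.

    ``lambdas`` maps condition name to either a scalar decay rate (applied
    to all genes) or a per-gene array.
    """
    ids = [g.gene_id for g in annotation.genes]
    genes = pd.DataFrame(
        {
            "is_expressed": np.ones(len(ids), dtype=bool),
            "cluster": np.zeros(len(ids), dtype=int),
            "baseline": np.full(len(ids), coverage_baseline),
            "coverage_baseline": np.full(len(ids), coverage_baseline),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    for cond, lam in lambdas.items():
        genes[f"lambda.{cond}"] = np.broadcast_to(np.asarray(lam, float), (len(ids),)).copy()
    return SyntheticTruth(genes, conditions=list(lambdas))


def plant_drug_truth(
    drugs: dict[str, dict] | None = None,
    combos: dict[str, dict] | None = None,
) -> SyntheticTruth:
    """Planted median-effect parameters and combination interaction modes.

    ``drugs``: name -> {"m": Hill slope, "dm": median-effect dose}.
    ``combos``: name -> {"drug1", "drug2", "mode", "target_ci"} where mode
    is additive (CI 1), synergistic (CI < 1) or antagonistic (CI > 1).
    """
    if drugs is None:
        drugs = {
            "thz531": {"m": 2.0, "dm": 50.0},
            "cisplatin": {"m": 1.5, "dm": 2000.0},
        }
    if combos is None:
        combos = {
            "thz531+cisplatin": {
                "drug1": "thz531",
                "drug2": "cisplatin",
                "mode": "synergistic",
                "target_ci": 0.5,
            }
        }
    for name, combo in combos.items():
        mode = combo.get("mode", "additive")
        if mode == "additive":
            combo["target_ci"] = 1.0
        elif "target_ci" not in combo:
            raise ValueError(f"combo {name}: non-additive mode needs target_ci")
    empty = pd.DataFrame(index=pd.Index([], name="gene_id"))
    return SyntheticTruth(empty, drugs=dict(drugs), combos=dict(combos))


# ---------------------------------------------------------------------------
# coverage


def _expected_gene_depth(gene: GeneModel, baseline: float, lam: float) -> np.ndarray:
    """Expected depth over the gene body in genomic orientation."""
    length = gene.length
    x = (np.arange(length) + 0.5) / length  # fractional position from TSS
    mu = baseline * np.exp(-lam * x)
    return mu[::-1] if gene.strand == "-" else mu


def simulate_coverage(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    condition: str,
    noise: bool = True,
    intergenic_rate: float = 0.1,
    seed: int = 0,
) -> CoverageTrack:
    """Per-base coverage under the exponential-decay processivity model.

    Gene-body bases carry Poisson(baseline * exp(-lam * x)) signal oriented
    from the TSS; intergenic bases carry Poisson(intergenic_rate).  With
    ``noise=False`` the expected values are emitted exactly.  The library's
    ``total_mapped_reads`` is the rounded total depth (depth is expressed in
    single-base read units), keeping per-million scaling consistent with the
    simulated signal.
    """
    rng = np.random.default_rng(seed)
    lam = truth.decay(condition)
    baseline = (
        truth.genes["coverage_baseline"]
        if "coverage_baseline" in truth.genes.columns
        else truth.genes["baseline"]
    )
    depth = {}
    for chrom, size in annotation.chrom_sizes.items():
        if noise and intergenic_rate > 0:
            depth[chrom] = rng.poisson(intergenic_rate, size=size).astype(float)
        else:
            depth[chrom] = np.full(size, float(intergenic_rate))
    for gene in annotation.genes:
        if gene.gene_id in truth.genes.index and not bool(
            truth.genes.loc[gene.gene_id, "is_expressed"]
        ):
            continue
        mu = _expected_gene_depth(
            gene, float(baseline.get(gene.gene_id, 0.0)), float(lam.get(gene.gene_id, 0.0))
        )
        signal = rng.poisson(mu).astype(float) if noise else mu
        depth[gene.chrom][gene.start : gene.end] = signal
    total = max(1, int(round(sum(arr.sum() for arr in depth.values()))))
    return CoverageTrack(depth, total)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    design: pd.DataFrame,
    nb_dispersion: float = 0.05,
    n_spike_ins: int = 20,
    spike_in_mean: float = 500.0,
    depth_multiplier_sd: float = 0.15,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial counts with planted fold-changes and spike-ins.

    ``design`` is indexed by sample id with a ``condition`` column (and an
    optional ``group`` column).  Each sample draws a log-normal depth
    multiplier (recorded in ``truth.depth_multipliers``); gene means are
    ``multiplier * baseline * 2**effect(condition)``.  Spike-in genes
    (``ERCC-like``) are constant in expectation across conditions and
    follow only the depth multiplier.  ``nb_dispersion`` is the NB
    dispersion alpha (variance = mu + alpha * mu^2); alpha = 0 falls back
    to Poisson.
    """
    if "condition" not in design.columns:
        raise ValueError("design needs a 'condition' column")
    counts_per_cond = design["condition"].value_counts()
    if (counts_per_cond < 2).any():
        raise ValueError("every condition needs >= 2 replicates")
    rng = np.random.default_rng(seed)
    samples = list(design.index)
    multipliers = np.exp(rng.normal(0.0, depth_multiplier_sd, size=len(samples)))
    truth.depth_multipliers = {s: float(m) for s, m in zip(samples, multipliers)}

    gene_ids = list(truth.genes.index)
    baseline = truth.genes["baseline"].to_numpy(float)
    mean_matrix = np.empty((len(gene_ids), len(samples)))
    for j, s in enumerate(samples):
        cond = str(design.loc[s, "condition"])
        eff = truth.effect(cond).to_numpy(float)
        mean_matrix[:, j] = multipliers[j] * baseline * np.exp2(eff)

    spike_ids = [f"ERCC-{i:04d}" for i in range(n_spike_ins)]
    if n_spike_ins:
        spike_base = rng.lognormal(np.log(spike_in_mean), 0.5, size=n_spike_ins)
        spike_means = np.outer(spike_base, multipliers)
        mean_matrix = np.vstack([mean_matrix, spike_means])
        gene_ids = gene_ids + spike_ids

    if nb_dispersion > 0:
        size = 1.0 / nb_dispersion
        p = size / (size + mean_matrix)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mean_matrix)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return CountMatrix(df, design.copy(), frozenset(spike_ids))


def three_group_design(
    n_tumor: int = 16, n_fetal: int = 4, n_adult: int = 5
) -> pd.DataFrame:
    """Default patient-cohort design: 16 tumors, 4 fetal and 5 adult controls."""
    rows = (
        [(f"tumor_{i+1:02d}", "tumor") for i in range(n_tumor)]
        + [(f"fetal_{i+1:02d}", "fetal") for i in range(n_fetal)]
        + [(f"adult_{i+1:02d}", "adult") for i in range(n_adult)]
    )
    df = pd.DataFrame(rows, columns=["sample", "condition"]).set_index("sample")
    df["group"] = df["condition"]
    return df


# ---------------------------------------------------------------------------
# dose-response


def hill_fraction_affected(dose, m: float, dm: float):
    """Median-effect model: fa = 1 / (1 + (Dm/D)^m); fa(Dm) = 0.5 exactly."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        fa = 1.0 / (1.0 + (dm / dose) ** m)
    return np.where(dose > 0, fa, 0.0)


def _dose_for_fa(fa: float, m: float, dm: float) -> float:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def loewe_fraction_affected(
    d1: float, d2: float, m1: float, dm1: float, m2: float, dm2: float,
    target_ci: float = 1.0,
) -> float:
    """Effect of a combination (d1, d2) constructed to yield a chosen CI.

    Solves ``d1/Dx1(fa) + d2/Dx2(fa) = target_ci`` for fa, where
    ``Dx_i(fa)`` is the single-agent dose of drug i producing effect fa.
    ``target_ci = 1`` is exact Loewe additivity; smaller targets plant
    synergy, larger antagonism.
    """
    if d1 <= 0 and d2 <= 0:
        return 0.0
    if d2 <= 0:
        return float(hill_fraction_affected(d1 / target_ci, m1, dm1))
    if d1 <= 0:
        return float(hill_fraction_affected(d2 / target_ci, m2, dm2))

    def excess(fa: float) -> float:
        return d1 / _dose_for_fa(fa, m1, dm1) + d2 / _dose_for_fa(fa, m2, dm2) - target_ci

    lo, hi = 1e-9, 1.0 - 1e-9
    return float(brentq(excess, lo, hi, xtol=1e-12, rtol=1e-14))


def simulate_dose_response(
    truth: SyntheticTruth,
    doses: dict[str, list[float]],
    combo_doses: dict[str, list[tuple[float, float]]] | None = None,
    replicate_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Viability tables for single agents and combinations.

    Returns ``{"single": long table (drug, dose, replicate, viability),
    "combo": long table (combo, drug1, drug2, dose1, dose2, replicate,
    viability)}``.  Noise is multiplicative log-normal (mean 1) on the
    fraction affected with coefficient of variation ``replicate_cv``
    (0 = noise-free); viability = 1 - fa.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(replicate_cv**2))

    def noisy(fa: float) -> float:
        """Viability after multiplicative noise on the fraction affected."""
        if replicate_cv > 0:
            fa = min(1.0, fa * float(rng.lognormal(-sigma**2 / 2.0, sigma)))
        return 1.0 - fa

    single_rows = []
    for drug, dlist in doses.items():
        m, dm = truth.drugs[drug]["m"], truth.drugs[drug]["dm"]
        for d in dlist:
            fa = float(hill_fraction_affected(d, m, dm))
            for rep in range(1, n_replicates + 1):
                single_rows.append((drug, float(d), rep, noisy(fa)))
    single = pd.DataFrame(single_rows, columns=["drug", "dose", "replicate", "viability"])

    combo_rows = []
    if combo_doses:
        for name, points in combo_doses.items():
            spec = truth.combos[name]
            d1_drug, d2_drug = spec["drug1"], spec["drug2"]
            m1, dm1 = truth.drugs[d1_drug]["m"], truth.drugs[d1_drug]["dm"]
            m2, dm2 = truth.drugs[d2_drug]["m"], truth.drugs[d2_drug]["dm"]
            for d1, d2 in points:
                fa = loewe_fraction_affected(
                    d1, d2, m1, dm1, m2, dm2, target_ci=float(spec["target_ci"])
                )
                for rep in range(1, n_replicates + 1):
                    combo_rows.append(
                        (name, d1_drug, d2_drug, float(d1), float(d2), rep, noisy(fa))
                    )
    combo = pd.DataFrame(
        combo_rows,
        columns=["combo", "drug1", "drug2", "dose1", "dose2", "replicate", "viability"],
    )
    return {"single": single, "combo": combo}
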