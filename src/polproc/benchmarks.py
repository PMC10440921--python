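"""Planted-truth benchmarks exercising every pipeline stage end to end.

Each function simulates data under the generator's study conditions, runs
the corresponding analysis stage, and returns the measured quantities next
to their closed-form or planted expectations.  The acceptance script and
the acceptance test suite both consume these functions, so the numbers
they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .diffexp import PRESETS, call_status, de_test
from .expression import background_threshold, coverage_fpkm
from .integration import apply_threshold, cluster_genes, perturbation_scores
from .metagene import metagene_profile, processivity_table
from .models import CoverageTrack, GeneModel, GenomeAnnotation
from .simulate import (
    hill_fraction_affected,
    plant_drug_truth,
    plant_expression_truth,
    plant_processivity_truth,
    simulate_annotation,
    simulate_counts,
    simulate_coverage,
    simulate_dose_response,
    three_group_design,
)
from .synergy import combination_index, fa_from_viability, fit_median_effect

__all__ = [
    "flat_profile_benchmark",
    "strand_symmetry_benchmark",
    "processivity_sweep_benchmark",
    "treatment_contrast_benchmark",
    "cluster_recovery_benchmark",
    "de_calibration_benchmark",
    "expression_filter_benchmark",
    "synergy_benchmark",
]


def flat_profile_benchmark(seed: int = 0, n_genes: int = 12) -> dict:
    """Uniform coverage must yield exactly 100/n_bins percent per bin."""
    ann = simulate_annotation(n_genes, {"chr1": 300_000}, seed=seed)
    truth = plant_processivity_truth(ann, {"c": 0.0}, 80.0)
    track = simulate_coverage(ann, truth, "c", noise=False, intergenic_rate=0.0)
    profile = metagene_profile(track, ann.genes)
    dev = float(np.abs(profile.per_gene.to_numpy() - 2.0).max())
    return {"max_abs_dev_percent": dev, "n_genes": len(profile.per_gene)}


def strand_symmetry_benchmark(seed: int = 0, length: int = 5000) -> dict:
    """A minus-strand gene with mirrored coverage must reproduce the
    plus-strand profile bin for bin."""
    rng = np.random.default_rng(seed)
    pattern = rng.poisson(60.0, length).astype(float)
    plus = GeneModel("plus", "chr1", 0, length, "+")
    minus = GeneModel("minus", "chr1", 2 * length, 3 * length, "-")
    ann = GenomeAnnotation([plus, minus], {"chr1": 4 * length})
    depth = np.zeros(4 * length)
    depth[:length] = pattern
    depth[2 * length : 3 * length] = pattern[::-1]
    track = CoverageTrack({"chr1": depth}, 1_000_000)
    profile = metagene_profile(track, [plus, minus])
    dev = float(
        np.abs(
            profile.per_gene.loc["plus"].to_numpy()
            - profile.per_gene.loc["minus"].to_numpy()
        ).max()
    )
    return {"max_abs_dev_percent": dev, "gene_length": length}


def _ratio_annotation(n_genes: int, length: int = 10_000) -> GenomeAnnotation:
    genes = [
        GeneModel(f"g{i}", "chr1", i * (length + 2000), i * (length + 2000) + length,
                  "+" if i % 2 == 0 else "-")
        for i in range(n_genes)
    ]
    return GenomeAnnotation(genes, {"chr1": n_genes * (length + 2000)})


def processivity_sweep_benchmark(
    seed: int = 0,
    lambdas: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    baseline: float = 100.0,
    n_genes: int = 40,
) -> dict:
    """Distal/proximal ratios under Poisson noise vs the exp(-0.8 lam)
    closed form of the decay model (windows 0.05-0.15 and 0.85-0.95)."""
    ann = _ratio_annotation(n_genes)
    results = {}
    for i, lam in enumerate(lambdas):
        truth = plant_processivity_truth(ann, {"c": lam}, baseline)
        track = simulate_coverage(
            ann, truth, "c", noise=True, intergenic_rate=0.0, seed=seed + i
        )
        table = processivity_table(track, ann.genes)
        results[lam] = {
            "mean_ratio": float(table["ratio"].mean()),
            "expected": float(np.exp(-0.8 * lam)),
        }
    rel_errs = [
        abs(r["mean_ratio"] / r["expected"] - 1.0) for r in results.values()
    ]
    ratios = [r["mean_ratio"] for r in results.values()]
    return {
        "per_lambda": results,
        "max_rel_err": float(max(rel_errs)),
        "strictly_decreasing": bool(all(a > b for a, b in zip(ratios, ratios[1:]))),
        "n_genes": n_genes,
    }


def treatment_contrast_benchmark(
    seed: int = 0, lambda_control: float = 1.0, baseline: float = 100.0,
    n_genes: int = 40,
) -> dict:
    """Doubling the decay rate (treatment) must scale the ratio by the
    closed-form factor exp(-0.8 * lambda_control)."""
    ann = _ratio_annotation(n_genes)
    truth = plant_processivity_truth(
        ann, {"control": lambda_control, "treated": 2.0 * lambda_control}, baseline
    )
    tables = {}
    for i, cond in enumerate(("control", "treated")):
        track = simulate_coverage(
            ann, truth, cond, noise=True, intergenic_rate=0.0, seed=seed + i
        )
        tables[cond] = processivity_table(track, ann.genes)
    fold = float(
        (tables["treated"]["ratio"] / tables["control"]["ratio"]).mean()
    )
    expected = float(np.exp(-0.8 * lambda_control))
    return {
        "mean_fold_change": fold,
        "expected": expected,
        "rel_err": abs(fold / expected - 1.0),
        "n_genes": n_genes,
    }


def cluster_recovery_benchmark(
    seed: int = 0,
    n_genes: int = 400,
    n_per_cluster: int = 25,
    amplitude: float = 3.0,
    n_restarts: int = 25,
) -> dict:
    """The full perturbation-score -> threshold -> k-means pipeline on
    three-group counts with four planted co-regulation patterns.

    Reports the retention rate of planted common DEGs, the adjusted Rand
    index of the recovered clusters against the planted partition, and
    whether the sample dendrogram cut at three recovers the groups.
    """
    ann = simulate_annotation(
        n_genes, {"chr1": 2_500_000, "chr2": 2_500_000}, seed=seed
    )
    truth = plant_expression_truth(
        ann, n_per_cluster=n_per_cluster, amplitude=amplitude, seed=seed + 1
    )
    design = three_group_design()
    counts = simulate_counts(ann, truth, design, seed=seed + 2)
    preset = PRESETS["patients_ega"]
    comparisons = {}
    for ref in ("fetal", "adult"):
        res = de_test(counts, ref, "tumor", method=preset["method"])
        res = call_status(res, preset["fc_threshold"], preset["p_threshold"],
                          preset["use_fdr"])
        comparisons[res.name] = res
    pt = apply_threshold(perturbation_scores(comparisons))
    retained = pt.retained()

    planted = truth.genes.index[truth.genes["cluster"] > 0]
    recall = float(len(retained.intersection(planted)) / len(planted))

    logc = np.log2(counts.biological().loc[retained] + 1.0)
    assignment = cluster_genes(logc, k=4, n_restarts=n_restarts, seed=seed + 3)
    eval_genes = retained.intersection(planted)
    ari = float(
        adjusted_rand_score(
            truth.genes.loc[eval_genes, "cluster"],
            assignment.gene_clusters.loc[eval_genes],
        )
    )
    groups = assignment.sample_groups(3)
    conditions = design.loc[groups.index, "condition"]
    separated = bool(
        conditions.groupby(groups).nunique().eq(1).all() and groups.nunique() == 3
    )
    return {
        "common_deg_recall": recall,
        "ari": ari,
        "groups_separated": separated,
        "threshold": pt.threshold,
        "youden_j": pt.youden_j,
        "n_retained": int(len(retained)),
        "restart_stability_ari": assignment.restart_stability,
        "n_planted": int(len(planted)),
    }


def de_calibration_benchmark(
    seed: int = 0,
    n_genes: int = 2000,
    n_rep: int = 5,
    frac_planted: float = 0.1,
    planted_log2fc: float = 2.0,
    dispersion: float = 0.05,
) -> dict:
    """Type-I error under the null and sensitivity for planted
    |log2FC| = 2 genes at FDR < 0.05, with 5 vs 5 replicates."""
    rng = np.random.default_rng(seed)
    ann = simulate_annotation(
        n_genes, {"chr1": 20_000_000, "chr2": 20_000_000}, seed=seed
    )
    ids = [g.gene_id for g in ann.genes]
    n_planted = int(round(frac_planted * n_genes))
    effect = np.zeros(n_genes)
    chosen = rng.choice(n_genes, size=n_planted, replace=False)
    signs = np.where(rng.random(n_planted) < 0.5, 1.0, -1.0)
    effect[chosen] = signs * planted_log2fc
    genes = pd.DataFrame(
        {
            "is_expressed": True,
            "cluster": 0,
            "baseline": rng.lognormal(5.5, 1.0, n_genes),
            "effect.ctrl": 0.0,
            "effect.trt": effect,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    from .simulate import SyntheticTruth

    truth = SyntheticTruth(genes, ["ctrl", "trt"])
    design = pd.DataFrame(
        {"condition": ["ctrl"] * n_rep + ["trt"] * n_rep},
        index=[f"s{i}" for i in range(2 * n_rep)],
    )
    counts = simulate_counts(ann, truth, design, nb_dispersion=dispersion,
                             seed=seed + 1)
    res = de_test(counts, "ctrl", "trt", method="nb_wald")
    null_ids = [g for g, e in zip(ids, effect) if e == 0]
    planted_ids = [g for g, e in zip(ids, effect) if e != 0]
    null_fraction = float((res.table.loc[null_ids, "p"] <= 0.05).mean())
    hits = res.table.loc[planted_ids]
    correct_sign = np.sign(hits["log2fc"]) == np.sign(
        truth.genes.loc[planted_ids, "effect.trt"]
    )
    sensitivity = float(((hits["fdr"] < 0.05) & correct_sign).mean())
    return {
        "null_fraction_p05": null_fraction,
        "sensitivity_fdr05": sensitivity,
        "n_null": len(null_ids),
        "n_planted": len(planted_ids),
    }


def expression_filter_benchmark(
    seed: int = 0,
    n_genes: int = 150,
    baseline_depth: float = 100.0,
    intergenic_rate: float = 10.0,
) -> dict:
    """Background threshold correctness and filter recovery.

    The intergenic Poisson rate is ten-fold below the gene-body signal;
    the 98th-percentile background cut must match an independent
    sort-and-interpolate computation exactly, pass planted-expressed genes
    and reject planted-silent ones.
    """
    ann = simulate_annotation(n_genes, {"chr1": 1_500_000, "chr2": 1_500_000}, seed=seed)
    truth = plant_expression_truth(
        ann, n_per_cluster=5, frac_silent=0.2, seed=seed + 1
    )
    cov_truth = plant_processivity_truth(ann, {"c": 0.0}, baseline_depth)
    cov_truth.genes["is_expressed"] = truth.genes["is_expressed"]
    track = simulate_coverage(
        ann, cov_truth, "c", noise=True, intergenic_rate=intergenic_rate, seed=seed + 2
    )
    bg = background_threshold(track, ann, min_segment_length=200)

    # independent quantile: re-derive segments by complement arithmetic and
    # apply the textbook sort-and-interpolate percentile
    segments = []
    for chrom, size in ann.chrom_sizes.items():
        spans = sorted((g.start, g.end) for g in ann.genes if g.chrom == chrom)
        cursor = 0
        for s, e in spans:
            if s - cursor >= 200:
                segments.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if size - cursor >= 200:
            segments.append((chrom, cursor, size))
    values = np.sort(coverage_fpkm(track, segments))
    rank = 0.98 * (len(values) - 1)
    lo = int(np.floor(rank))
    independent = values[lo] + (rank - lo) * (values[min(lo + 1, len(values) - 1)] - values[lo])

    gene_fpkm = pd.Series(
        coverage_fpkm(track, [(g.chrom, g.start, g.end) for g in ann.genes]),
        index=[g.gene_id for g in ann.genes],
    )
    expressed_call = gene_fpkm > bg.threshold
    is_expr = truth.genes["is_expressed"]
    pass_rate = float(expressed_call[is_expr].mean())
    fail_rate = float((~expressed_call[~is_expr]).mean())
    return {
        "threshold": bg.threshold,
        "independent_threshold": float(independent),
        "threshold_abs_diff": abs(bg.threshold - float(independent)),
        "expressed_pass_rate": pass_rate,
        "silent_fail_rate": fail_rate,
        "n_segments": int(len(bg.intergenic_fpkm)),
        "n_genes": n_genes,
    }


def synergy_benchmark(seed: int = 0) -> dict:
    """Sham-combination identity, exact noise-free median-effect fits, and
    recovery of a planted combination index of 0.5."""
    m, dm = 2.0, 50.0
    doses = np.array([12.5, 25.0, 50.0, 100.0, 200.0])
    curve = fit_median_effect(doses, hill_fraction_affected(doses, m, dm))
    sham_points = pd.DataFrame(
        {"dose1": doses / 2, "dose2": doses / 2,
         "fa": hill_fraction_affected(doses, m, dm)}
    )
    sham = combination_index(curve, curve, sham_points)
    sham_dev = float(np.abs(sham.points["ci"] - 1.0).max())

    truth = plant_drug_truth()  # synergistic combo, target CI 0.5
    combo = next(iter(truth.combos))
    tables = simulate_dose_response(
        truth,
        {"thz531": [12.5, 25, 50, 100, 200],
         "cisplatin": [500, 1000, 2000, 4000, 8000]},
        {combo: [(50.0, d2) for d2 in (500, 1000, 2000, 4000)]},
        replicate_cv=0.0,
        n_replicates=1,
        seed=seed,
    )
    curves = {}
    fit_errs = []
    for drug, sub in tables["single"].groupby("drug"):
        mean_v = sub.groupby("dose")["viability"].mean()
        c = fit_median_effect(mean_v.index.to_numpy(), fa_from_viability(mean_v))
        curves[drug] = c
        fit_errs.append(abs(c.m / truth.drugs[drug]["m"] - 1.0))
        fit_errs.append(abs(c.dm / truth.drugs[drug]["dm"] - 1.0))
    pts = tables["combo"].groupby(["dose1", "dose2"])["viability"].mean().reset_index()
    pts["fa"] = 1.0 - pts["viability"]
    ci = combination_index(curves["thz531"], curves["cisplatin"], pts)
    return {
        "sham_ci_max_abs_dev": sham_dev,
        "fit_max_rel_err": float(max(fit_errs)),
        "recovered_ci": ci.mean_ci,
        "target_ci": float(truth.combos[combo]["target_ci"]),
        "ci_abs_err": abs(ci.mean_ci - float(truth.combos[combo]["target_ci"])),
    }
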