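"""Configuration-driven orchestration of the analysis stages.

``run_workflow`` drives the full synthetic-benchmark pipeline: simulate an
annotated genome with planted truth, quantify and filter expression against
the intergenic background, run the per-contrast DE tests, integrate them
into perturbation scores and clusters, profile metagene coverage and
processivity ratios under control and treated conditions, test gene-set
overlaps, and score drug-combination synergy.  Every stage writes TSV/JSON
outputs into the run directory and contributes record counts to the run
report; given fixed seeds the outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .diffexp import PRESETS, call_status, de_test
from .expression import background_threshold, compute_fpkm, filter_expressed
from .integration import (
    apply_threshold,
    cluster_genes,
    linkage_to_newick,
    perturbation_scores,
)
from .metagene import metagene_profile, processivity_table
from .overlap import overlap_test
from .simulate import (
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

__all__ = ["default_config", "validate_config", "run_workflow"]


def default_config(seed: int = 0) -> dict:
    """The bundled demo configuration: a small three-group cohort plus a
    two-condition processivity contrast and one drug combination."""
    return {
        "seed": seed,
        "genome": {"chrom_sizes": {"chr1": 600_000, "chr2": 600_000}, "n_genes": 120},
        "expression": {
            "n_per_cluster": 15,
            "amplitude": 3.0,
            "frac_silent": 0.1,
            "nb_dispersion": 0.05,
            "design": {"n_tumor": 16, "n_fetal": 4, "n_adult": 5},
        },
        "processivity": {
            "lambda_control": 1.0,
            "lambda_treated": 2.0,
            "baseline_depth": 100.0,
            "intergenic_rate": 0.1,
            "n_bins": 50,
            "proximal_window": [0.05, 0.15],
            "distal_window": [0.85, 0.95],
        },
        "integration": {"k": 4, "n_restarts": 25, "preset": "patients_ega"},
        "synergy": {
            "doses1": [12.5, 25.0, 50.0, 100.0, 200.0],
            "doses2": [500.0, 1000.0, 2000.0, 4000.0, 8000.0],
            "fixed_dose1": 50.0,
            "replicate_cv": 0.0,
        },
    }


_REQUIRED_SECTIONS = ("genome", "expression", "processivity", "integration", "synergy")


def validate_config(config: dict) -> dict:
    """Fill defaults and reject structurally invalid configurations."""
    merged = default_config(int(config.get("seed", 0)))
    for section in _REQUIRED_SECTIONS:
        user = config.get(section, {})
        if not isinstance(user, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(user) - set(merged[section])
        if unknown:
            raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
        merged[section].update(user)
    if merged["genome"]["n_genes"] < 4 * merged["expression"]["n_per_cluster"]:
        raise ValueError("n_genes must cover four planted clusters")
    return merged


def run_workflow(config: dict, outdir) -> dict:
    """Run the full synthetic benchmark; returns the run report dict."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    stage_seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("annotation", "truth", "counts", "coverage", "cluster", "dose")
    }
    report: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": config,
        "stages": {},
    }
    t0 = time.time()

    # --- simulate ---------------------------------------------------------
    genome = config["genome"]
    annotation = simulate_annotation(
        genome["n_genes"], dict(genome["chrom_sizes"]), seed=stage_seeds["annotation"]
    )
    pio.write_gene_models(annotation, outdir / "genes.gtf")
    pio.write_chrom_sizes(annotation.chrom_sizes, outdir / "chrom.sizes")

    expr_cfg = config["expression"]
    truth = plant_expression_truth(
        annotation,
        n_per_cluster=expr_cfg["n_per_cluster"],
        amplitude=expr_cfg["amplitude"],
        frac_silent=expr_cfg["frac_silent"],
        seed=stage_seeds["truth"],
    )
    design = three_group_design(**expr_cfg["design"])
    counts = simulate_counts(
        annotation,
        truth,
        design,
        nb_dispersion=expr_cfg["nb_dispersion"],
        seed=stage_seeds["counts"],
    )
    pio.write_counts(counts, outdir / "counts.tsv", outdir / "samples.tsv")

    proc_cfg = config["processivity"]
    cov_truth = plant_processivity_truth(
        annotation,
        {
            "control": proc_cfg["lambda_control"],
            "treated": proc_cfg["lambda_treated"],
        },
        coverage_baseline=proc_cfg["baseline_depth"],
    )
    tracks = {}
    for i, cond in enumerate(("control", "treated")):
        tracks[cond] = simulate_coverage(
            annotation,
            cov_truth,
            cond,
            intergenic_rate=proc_cfg["intergenic_rate"],
            seed=stage_seeds["coverage"] + i,
        )
        pio.write_bedgraph(tracks[cond], outdir / f"coverage_{cond}.bedgraph")
        (outdir / f"coverage_{cond}.total_reads").write_text(
            f"{tracks[cond].total_mapped_reads}\n"
        )
    pio.write_json(truth.to_dict(), outdir / "truth.json")
    report["stages"]["simulate"] = {
        "n_genes": len(annotation),
        "n_samples": len(design),
        "total_mapped_reads": {c: t.total_mapped_reads for c, t in tracks.items()},
    }

    # --- quantify + background filter ------------------------------------
    expr = compute_fpkm(counts, annotation)
    expr.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
    expr.cpm.to_csv(outdir / "cpm.tsv", sep="\t")
    background = background_threshold(tracks["control"], annotation)
    calls = filter_expressed(expr, background, ("tumor", "fetal"))
    expressed_universe = list(calls.index[calls["expressed"]])
    (outdir / "expressed_genes.txt").write_text("\n".join(expressed_universe) + "\n")
    pio.write_json(
        {
            "background_threshold_fpkm": background.threshold,
            "n_intergenic_segments": int(len(background.intergenic_fpkm)),
            "n_expressed": len(expressed_universe),
        },
        outdir / "background.json",
    )
    report["stages"]["quantify"] = {
        "background_threshold": background.threshold,
        "n_expressed": len(expressed_universe),
    }

    # --- differential expression ------------------------------------------
    preset = PRESETS[config["integration"]["preset"]]
    comparisons = {}
    for ref in ("fetal", "adult"):
        res = de_test(counts, ref, "tumor", method=preset["method"])
        res = call_status(
            res,
            fc_threshold=preset["fc_threshold"],
            p_threshold=preset["p_threshold"],
            use_fdr=preset["use_fdr"],
        )
        res.table.to_csv(outdir / f"de_tumor_vs_{ref}.tsv", sep="\t")
        comparisons[res.name] = res
    report["stages"]["de"] = {
        name: {"n_degs": int(len(res.degs()))} for name, res in comparisons.items()
    }

    # --- integration -------------------------------------------------------
    pt = apply_threshold(perturbation_scores(comparisons))
    pt.table.to_csv(outdir / "perturbation.tsv", sep="\t")
    retained = pt.retained()
    lib = counts.biological().sum(axis=0)
    logc = np.log2(counts.biological().loc[retained] + 1.0)
    assignment = cluster_genes(
        logc,
        k=config["integration"]["k"],
        n_restarts=config["integration"]["n_restarts"],
        seed=stage_seeds["cluster"],
    )
    assignment.gene_clusters.to_csv(outdir / "clusters.tsv", sep="\t")
    (outdir / "sample_dendrogram.nwk").write_text(
        linkage_to_newick(assignment.sample_linkage, list(assignment.standardized.columns))
        + "\n"
    )
    report["stages"]["integrate"] = {
        "threshold": pt.threshold,
        "youden_j": pt.youden_j,
        "n_retained": int(len(retained)),
        "restart_stability_ari": assignment.restart_stability,
    }

    # --- metagene + processivity ------------------------------------------
    prox = tuple(proc_cfg["proximal_window"])
    dist = tuple(proc_cfg["distal_window"])
    usable = [g for g in annotation.genes if g.length >= proc_cfg["n_bins"]]
    ratios = {}
    for cond in ("control", "treated"):
        profile = metagene_profile(tracks[cond], usable, proc_cfg["n_bins"], cond)
        pd.DataFrame(
            {"bin": np.arange(1, proc_cfg["n_bins"] + 1), "percent": profile.aggregate}
        ).to_csv(outdir / f"metagene_{cond}.tsv", sep="\t", index=False)
        ratios[cond] = processivity_table(tracks[cond], usable, prox, dist)
        ratios[cond].to_csv(outdir / f"procratio_{cond}.tsv", sep="\t")
    fold = (ratios["treated"]["ratio"] / ratios["control"]["ratio"]).rename("ratio_fold_change")
    fold.to_csv(outdir / "procratio_foldchange.tsv", sep="\t")
    report["stages"]["metagene"] = {
        "n_profiled": int(len(usable)),
        "median_ratio": {c: float(r["ratio"].median()) for c, r in ratios.items()},
        "median_ratio_fold_change": float(fold.median()),
    }

    # --- overlap ------------------------------------------------------------
    predicted = set(retained)
    planted = set(truth.genes.index[truth.genes["cluster"] > 0])
    universe = set(pt.table.index)
    ov = overlap_test(predicted & universe, planted & universe, universe)
    pio.write_json({"predicted_vs_planted": ov.as_dict()}, outdir / "overlap.json")
    report["stages"]["overlap"] = ov.as_dict()

    # --- synergy ------------------------------------------------------------
    syn_cfg = config["synergy"]
    drug_truth = plant_drug_truth()
    combo_name = next(iter(drug_truth.combos))
    combo_points = [(syn_cfg["fixed_dose1"], d2) for d2 in syn_cfg["doses2"]]
    tables = simulate_dose_response(
        drug_truth,
        {"thz531": syn_cfg["doses1"], "cisplatin": syn_cfg["doses2"]},
        {combo_name: combo_points},
        replicate_cv=syn_cfg["replicate_cv"],
        seed=stage_seeds["dose"],
    )
    tables["single"].to_csv(outdir / "dose_response.tsv", sep="\t", index=False)
    tables["combo"].to_csv(outdir / "dose_response_combo.tsv", sep="\t", index=False)
    curves = {}
    for drug, sub in tables["single"].groupby("drug"):
        mean_v = sub.groupby("dose")["viability"].mean()
        curves[drug] = fit_median_effect(mean_v.index.to_numpy(), fa_from_viability(mean_v))
    combo_mean = (
        tables["combo"].groupby(["dose1", "dose2"])["viability"].mean().reset_index()
    )
    combo_mean["fa"] = 1.0 - combo_mean["viability"]
    ci = combination_index(
        curves["thz531"], curves["cisplatin"], combo_mean, drug1="thz531", drug2="cisplatin"
    )
    ci.points.to_csv(outdir / "combination_index.tsv", sep="\t", index=False)
    report["stages"]["synergy"] = {
        "fits": {d: {"m": c.m, "dm": c.dm, "r2": c.r_squared} for d, c in curves.items()},
        "mean_ci": ci.mean_ci,
        "target_ci": drug_truth.combos[combo_name]["target_ci"],
    }

    report["wall_time_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
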