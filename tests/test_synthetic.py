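import json

import numpy as np
import pandas as pd
import pytest

from polproc.simulate import (
    CLUSTER_SHAPES,
    SyntheticTruth,
    hill_fraction_affected,
    loewe_fraction_affected,
    plant_drug_truth,
    plant_expression_truth,
    plant_processivity_truth,
    simulate_annotation,
    simulate_counts,
    simulate_coverage,
    simulate_dose_response,
    three_group_design,
)


class TestAnnotation:
    def test_zero_genes(self):
        ann = simulate_annotation(0, {"chr1": 1000}, seed=0)
        assert len(ann) == 0

    def test_fixed_seed_is_deterministic(self):
        a = simulate_annotation(50, {"chr1": 500_000}, seed=42)
        b = simulate_annotation(50, {"chr1": 500_000}, seed=42)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in a.genes] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand) for g in b.genes
        ]

    def test_placement_invariants_and_intergenic_fraction(self):
        sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
        ann = simulate_annotation(200, sizes, seed=1)
        assert len(ann) == 200
        by_chrom = {}
        for g in ann.genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2, "genes overlap"
        footprint = sum(g.length for g in ann.genes)
        assert 1 - footprint / sum(sizes.values()) >= 0.30

    def test_impossible_footprint_raises(self):
        with pytest.raises(ValueError, match="70%"):
            simulate_annotation(100, {"chr1": 10_000}, seed=0)


class TestCoverage:
    def test_lambda_zero_noise_free_is_uniform(self, toy_annotation):
        truth = plant_processivity_truth(toy_annotation, {"c": 0.0}, 50.0)
        track = simulate_coverage(toy_annotation, truth, "c", noise=False, intergenic_rate=0.0)
        g = toy_annotation.get("gA")
        np.testing.assert_allclose(track.depth["chr1"][g.start : g.end], 50.0)

    def test_large_lambda_kills_distal_signal(self, toy_annotation):
        truth = plant_processivity_truth(toy_annotation, {"c": 2000.0}, 100.0)
        track = simulate_coverage(toy_annotation, truth, "c", noise=False, intergenic_rate=0.0)
        g = toy_annotation.get("gA")
        body = track.depth["chr1"][g.start : g.end]
        assert body[: g.length // 50].mean() > 1.0
        assert body[g.length // 50 :].max() < 1e-2

    def test_decay_ratio_matches_closed_form(self):
        ann = simulate_annotation(30, {"chr1": 800_000}, seed=3, length_meanlog=9.2)
        truth = plant_processivity_truth(ann, {"c": 1.0}, 150.0)
        track = simulate_coverage(ann, truth, "c", noise=True, intergenic_rate=0.0, seed=4)
        ratios = []
        for g in ann.genes:
            body = track.gene_depth(g)
            tenth = g.length // 10
            ratios.append(body[-tenth:].mean() / body[:tenth].mean())
        expected = np.exp(-0.9)  # distal tenth centered 0.95, proximal 0.05
        assert abs(np.mean(ratios) / expected - 1) < 0.05

    def test_fixed_seed_is_deterministic(self, toy_annotation):
        truth = plant_processivity_truth(toy_annotation, {"c": 1.0}, 20.0)
        t1 = simulate_coverage(toy_annotation, truth, "c", seed=9)
        t2 = simulate_coverage(toy_annotation, truth, "c", seed=9)
        for chrom in t1.depth:
            np.testing.assert_array_equal(t1.depth[chrom], t2.depth[chrom])
        assert t1.total_mapped_reads == t2.total_mapped_reads


class TestCounts:
    @staticmethod
    def _two_condition_truth(annotation, log2fc=1.0):
        ids = [g.gene_id for g in annotation.genes]
        genes = pd.DataFrame(
            {
                "is_expressed": True,
                "cluster": 0,
                "baseline": 200.0,
                "effect.a": 0.0,
                "effect.b": float(log2fc),
            },
            index=pd.Index(ids, name="gene_id"),
        )
        return SyntheticTruth(genes, ["a", "b"])

    def test_mean_ratio_approaches_planted_fold_change(self):
        ann = simulate_annotation(20, {"chr1": 200_000}, seed=0)
        truth = self._two_condition_truth(ann, log2fc=1.0)
        design = pd.DataFrame(
            {"condition": ["a"] * 200 + ["b"] * 200},
            index=[f"s{i}" for i in range(400)],
        )
        cm = simulate_counts(ann, truth, design, nb_dispersion=1e-8,
                             depth_multiplier_sd=0.0, seed=1)
        bio = cm.biological()
        ratio = bio[design.index[200:]].mean(axis=1) / bio[design.index[:200]].mean(axis=1)
        np.testing.assert_allclose(ratio, 2.0, rtol=0.05)

    def test_spike_ins_have_no_planted_fold_change(self):
        ann = simulate_annotation(10, {"chr1": 100_000}, seed=0)
        truth = self._two_condition_truth(ann, log2fc=2.0)
        design = pd.DataFrame(
            {"condition": ["a", "a", "b", "b"]}, index=["s1", "s2", "s3", "s4"]
        )
        cm = simulate_counts(ann, truth, design, seed=2)
        assert len(cm.spike_in_ids) == 20
        # planted truth never assigns an effect to spike-ins: their expected
        # count depends only on the sample depth multiplier
        assert all(g not in truth.genes.index for g in cm.spike_in_ids)

    def test_requires_two_replicates(self):
        ann = simulate_annotation(5, {"chr1": 100_000}, seed=0)
        truth = self._two_condition_truth(ann)
        design = pd.DataFrame({"condition": ["a", "b", "b"]}, index=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="2 replicates"):
            simulate_counts(ann, truth, design)

    def test_fixed_seed_is_deterministic(self):
        ann = simulate_annotation(10, {"chr1": 100_000}, seed=0)
        truth = self._two_condition_truth(ann)
        design = three_group_design(4, 2, 2)
        design["condition"] = ["a", "a", "b", "b", "a", "a", "b", "b"]
        c1 = simulate_counts(ann, truth, design, seed=5)
        c2 = simulate_counts(ann, truth, design, seed=5)
        assert c1.counts.equals(c2.counts)


class TestClusterTruth:
    def test_cluster_shapes_are_common_deg_directions(self):
        # every planted pattern must be regulated with one sign in both
        # tumor-vs-fetal and tumor-vs-adult contrasts
        for shape in CLUSTER_SHAPES.values():
            t, f, a = shape
            assert (t - f) * (t - a) > 0

    def test_planted_table_structure(self):
        ann = simulate_annotation(60, {"chr1": 600_000}, seed=2)
        truth = plant_expression_truth(ann, n_per_cluster=10, seed=3)
        counts = truth.genes["cluster"].value_counts()
        assert all(counts.get(c, 0) == 10 for c in (1, 2, 3, 4))
        silent = truth.genes[~truth.genes["is_expressed"]]
        assert (silent["cluster"] == 0).all()
        assert (silent["baseline"] < 1).all()

    def test_truth_round_trips_through_json(self):
        ann = simulate_annotation(20, {"chr1": 200_000}, seed=2)
        truth = plant_expression_truth(ann, n_per_cluster=4, seed=3)
        truth.drugs = {"d": {"m": 2.0, "dm": 10.0}}
        blob = json.dumps(truth.to_dict())
        back = SyntheticTruth.from_dict(json.loads(blob))
        pd.testing.assert_frame_equal(back.genes, truth.genes)
        assert back.drugs == truth.drugs


class TestDoseResponse:
    def test_fa_is_half_at_median_effect_dose(self):
        assert hill_fraction_affected(50.0, m=2.0, dm=50.0) == pytest.approx(0.5)

    def test_sham_self_combination_is_loewe_consistent(self):
        # a dose D split as D/2 + D/2 of the same drug reproduces fa(D)
        m, dm = 2.0, 50.0
        fa = loewe_fraction_affected(30.0, 30.0, m, dm, m, dm, target_ci=1.0)
        assert fa == pytest.approx(float(hill_fraction_affected(60.0, m, dm)), abs=1e-9)

    def test_noise_free_tables_reproduce_hill(self):
        truth = plant_drug_truth()
        tables = simulate_dose_response(
            truth, {"thz531": [25.0, 50.0, 100.0]}, replicate_cv=0.0, n_replicates=2
        )
        single = tables["single"]
        at_dm = single[single["dose"] == 50.0]["viability"]
        np.testing.assert_allclose(at_dm, 0.5)

    def test_fixed_seed_is_deterministic(self):
        truth = plant_drug_truth()
        kw = dict(doses={"thz531": [20.0, 50.0, 80.0]}, replicate_cv=0.1, seed=11)
        t1 = simulate_dose_response(truth, **kw)
        t2 = simulate_dose_response(truth, **kw)
        pd.testing.assert_frame_equal(t1["single"], t2["single"])
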