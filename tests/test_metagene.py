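import numpy as np
import pandas as pd
import pytest

from polproc.metagene import (
    bin_bounds,
    compare_gene_sets,
    metagene_profile,
    processivity_ratio,
    processivity_table,
)
from polproc.models import CoverageTrack, GeneModel, GenomeAnnotation
from polproc.simulate import plant_processivity_truth, simulate_coverage

from conftest import decay_track, make_track


class TestBinBounds:
    @pytest.mark.parametrize("length", [50, 73, 100, 5049])
    def test_bins_cover_gene_with_at_most_one_base_difference(self, length):
        bounds = bin_bounds(length, 50)
        sizes = np.diff(bounds)
        assert bounds[0] == 0 and bounds[-1] == length
        assert sizes.max() - sizes.min() <= 1
        # remainder bases go to the leading bins
        assert (np.sort(sizes)[::-1] == sizes).all()


class TestMetageneProfile:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_uniform_coverage_gives_exact_two_percent_bins(self, strand):
        gene = GeneModel("g", "chr1", 100, 5149, strand)  # length 5049, remainder 49
        ann = GenomeAnnotation([gene], {"chr1": 6000})
        track = make_track(ann, 0.0)
        track.depth["chr1"][gene.start : gene.end] = 7.3
        profile = metagene_profile(track, [gene])
        np.testing.assert_allclose(profile.aggregate, 2.0, atol=1e-9)

    def test_strand_symmetry_is_exact(self):
        rng = np.random.default_rng(0)
        pattern = rng.poisson(40.0, 3000).astype(float)
        plus = GeneModel("gp", "chr1", 0, 3000, "+")
        minus = GeneModel("gm", "chr1", 5000, 8000, "-")
        ann = GenomeAnnotation([plus, minus], {"chr1": 10_000})
        track = make_track(ann, 0.0)
        track.depth["chr1"][0:3000] = pattern
        track.depth["chr1"][5000:8000] = pattern[::-1]
        profile = metagene_profile(track, [plus, minus])
        np.testing.assert_array_equal(
            profile.per_gene.loc["gp"].to_numpy(), profile.per_gene.loc["gm"].to_numpy()
        )

    def test_decay_profile_matches_discretized_exponential(self):
        lam = 1.0
        genes = [
            GeneModel(f"g{i}", "chr1", i * 12_000, i * 12_000 + 10_000, "+")
            for i in range(30)
        ]
        ann = GenomeAnnotation(genes, {"chr1": 400_000})
        truth = plant_processivity_truth(ann, {"c": lam}, 150.0)
        track = simulate_coverage(ann, truth, "c", noise=True, intergenic_rate=0.0, seed=1)
        profile = metagene_profile(track, genes)
        edges = np.linspace(0, 1, 51)
        expected = np.diff(-np.exp(-lam * edges)) / (1 - np.exp(-lam)) * 100
        np.testing.assert_allclose(profile.aggregate, expected, rtol=0.05)

    def test_aggregate_invariant_to_gene_order_and_depth_scale(self, toy_annotation):
        track = decay_track(toy_annotation, 0.8)
        genes = list(toy_annotation.genes)
        p1 = metagene_profile(track, genes)
        p2 = metagene_profile(track, genes[::-1])
        np.testing.assert_allclose(p1.aggregate, p2.aggregate, atol=1e-12)
        scaled = CoverageTrack(
            {c: a * 7.0 for c, a in track.depth.items()}, track.total_mapped_reads
        )
        p3 = metagene_profile(scaled, genes)
        np.testing.assert_allclose(p1.aggregate, p3.aggregate, atol=1e-9)

    def test_short_genes_excluded_with_warning(self):
        long_g = GeneModel("long", "chr1", 0, 500, "+")
        short_g = GeneModel("short", "chr1", 600, 630, "+")
        ann = GenomeAnnotation([long_g, short_g], {"chr1": 1000})
        track = make_track(ann, 1.0)
        with pytest.warns(UserWarning, match="excluded"):
            profile = metagene_profile(track, [long_g, short_g])
        assert list(profile.per_gene.index) == ["long"]

    def test_empty_gene_set_after_filter_is_an_error(self):
        g = GeneModel("short", "chr1", 0, 30, "+")
        ann = GenomeAnnotation([g], {"chr1": 100})
        track = make_track(ann, 1.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable genes"):
                metagene_profile(track, [g])


class TestCompareGeneSets:
    def test_identical_sets_are_family_wide_nonsignificant(self):
        rng = np.random.default_rng(1)
        features = pd.DataFrame(
            {"length": rng.lognormal(9, 0.5, 60)},
            index=pd.Index([f"g{i}" for i in range(60)], name="gene_id"),
        )
        ids = list(features.index[:30])
        table = compare_gene_sets(features, {"down": ids, "up": ids, "unreg": ids})
        assert (table["p_holm"] == 1.0).all()

    def test_holm_step_down_adjustment_values(self):
        from polproc._stats import holm_adjust

        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_matched_length_sets_rarely_differ(self):
        # type-I error control: equal-length up/down sets should almost
        # never yield a significant pair
        rng = np.random.default_rng(2)
        n_sig = 0
        n_sim = 100
        ids = [f"g{i}" for i in range(300)]
        sets = {"down": ids[:100], "up": ids[100:200], "unregulated": ids[200:]}
        for _ in range(n_sim):
            features = pd.DataFrame(
                {"length": rng.lognormal(9, 0.6, 300)},
                index=pd.Index(ids, name="gene_id"),
            )
            table = compare_gene_sets(features, sets)
            n_sig += int((table["p_holm"] < 0.05).any())
        assert n_sig / n_sim <= 0.05


class TestProcessivityRatio:
    def test_uniform_coverage_gives_ratio_one(self, toy_annotation):
        track = make_track(toy_annotation, 5.0)
        m = processivity_ratio(track, toy_annotation.get("gA"))
        assert m.ratio == pytest.approx(1.0)
        assert m.defined

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_decay_ratio_matches_closed_form_noise_free(self, strand):
        gene = GeneModel("g", "chr1", 0, 10_000, strand)
        ann = GenomeAnnotation([gene], {"chr1": 12_000})
        track = decay_track(ann, 1.0)
        m = processivity_ratio(track, gene)
        assert m.ratio == pytest.approx(np.exp(-0.8), rel=1e-9)

    def test_ratio_strictly_decreasing_in_decay_rate(self, toy_annotation):
        ratios = []
        for lam in (0.0, 0.5, 1.0, 2.0):
            track = decay_track(toy_annotation, lam)
            ratios.append(processivity_ratio(track, toy_annotation.get("gA")).ratio)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_treated_versus_control_fold_change(self):
        gene = GeneModel("g", "chr1", 0, 10_000, "+")
        ann = GenomeAnnotation([gene], {"chr1": 12_000})
        control = processivity_ratio(decay_track(ann, 1.0), gene).ratio
        treated = processivity_ratio(decay_track(ann, 2.0), gene).ratio
        assert treated / control == pytest.approx(np.exp(-0.8), rel=1e-9)

    def test_total_reads_scaling_cancels_in_ratio(self, toy_annotation):
        g = toy_annotation.get("gA")
        t1 = decay_track(toy_annotation, 1.0, total_mapped_reads=1_000_000)
        t2 = decay_track(toy_annotation, 1.0, total_mapped_reads=2_000_000)
        m1, m2 = processivity_ratio(t1, g), processivity_ratio(t2, g)
        assert m2.proximal_signal == pytest.approx(m1.proximal_signal / 2)
        assert m2.ratio == pytest.approx(m1.ratio)

    def test_silent_gene_flagged_undefined(self, toy_annotation):
        track = make_track(toy_annotation, 0.0)
        m = processivity_ratio(track, toy_annotation.get("gA"))
        assert not m.defined
        assert np.isnan(m.ratio)

    def test_overlapping_windows_rejected(self, toy_annotation):
        track = make_track(toy_annotation, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            processivity_ratio(
                track, toy_annotation.get("gA"), (0.05, 0.5), (0.4, 0.9)
            )

    def test_table_collects_all_genes(self, toy_annotation):
        track = decay_track(toy_annotation, 0.5)
        table = processivity_table(track, toy_annotation.genes)
        assert len(table) == 3
        assert table["defined"].all()
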