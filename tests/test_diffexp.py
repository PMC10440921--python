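import numpy as np
import pandas as pd
import pytest

from polproc._stats import bh_adjust, holm_adjust
from polproc.diffexp import call_status, de_test, size_factors
from polproc.models import CountMatrix
from polproc.simulate import (
    SyntheticTruth,
    simulate_annotation,
    simulate_counts,
)


def brute_force_bh(p):
    """Reference BH: sort, p*n/rank, cumulative min from the largest."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def brute_force_holm(p):
    """Reference Holm: sort ascending, p*(n-i), running max, clip at 1."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * (n - np.arange(n))
    adj = np.maximum.accumulate(adj)
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestAdjustments:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bh_matches_brute_force(self, seed):
        p = np.random.default_rng(seed).uniform(size=500)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_holm_matches_brute_force(self, seed):
        p = np.random.default_rng(seed).uniform(size=200)
        np.testing.assert_allclose(holm_adjust(p), brute_force_holm(p), atol=1e-12)


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self, toy_counts):
        cm = CountMatrix(
            toy_counts.counts[["s1", "s1"]].set_axis(["x", "y"], axis=1),
            pd.DataFrame({"condition": ["c", "c"]}, index=["x", "y"]),
            toy_counts.spike_in_ids,
        )
        f = size_factors(cm, anchor="all_genes")
        assert f["x"] == pytest.approx(f["y"])

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [20, 40, 60]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
        meta = pd.DataFrame({"condition": ["c", "c"]}, index=["a", "b"])
        f = size_factors(CountMatrix(counts, meta), anchor="all_genes")
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_no_usable_anchor_is_an_error(self):
        counts = pd.DataFrame(
            {"a": [0, 1], "b": [1, 0]}, index=pd.Index(["g1", "g2"], name="gene_id")
        )
        meta = pd.DataFrame({"condition": ["c", "c"]}, index=["a", "b"])
        with pytest.raises(ValueError, match="anchor"):
            size_factors(CountMatrix(counts, meta), anchor="all_genes")

    def test_spike_anchored_factors_recover_planted_depths(self):
        ann = simulate_annotation(80, {"chr1": 800_000}, seed=0)
        ids = [g.gene_id for g in ann.genes]
        genes = pd.DataFrame(
            {
                "is_expressed": True,
                "cluster": 0,
                "baseline": np.random.default_rng(1).lognormal(6, 1, len(ids)),
                "effect.a": 0.0,
                "effect.b": np.random.default_rng(2).normal(0, 2, len(ids)),
            },
            index=pd.Index(ids, name="gene_id"),
        )
        truth = SyntheticTruth(genes, ["a", "b"])
        design = pd.DataFrame(
            {"condition": ["a"] * 4 + ["b"] * 4}, index=[f"s{i}" for i in range(8)]
        )
        cm = simulate_counts(ann, truth, design, nb_dispersion=0.01,
                             n_spike_ins=50, spike_in_mean=2000, seed=3)
        est = size_factors(cm, anchor="spike_ins")
        planted = pd.Series(truth.depth_multipliers)
        est_rel = est / np.exp(np.log(est).mean())
        planted_rel = planted / np.exp(np.log(planted).mean())
        np.testing.assert_allclose(est_rel, planted_rel.loc[est_rel.index], rtol=0.05)


class TestDeTest:
    @staticmethod
    def _null_counts(n_genes=400, n_rep=5, seed=0, dispersion=0.05):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(5.5, 1, n_genes)
        size = 1 / dispersion
        mu = np.tile(base[:, None], (1, 2 * n_rep))
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mu)),
            index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
            columns=[f"s{i}" for i in range(2 * n_rep)],
        )
        meta = pd.DataFrame(
            {"condition": ["a"] * n_rep + ["b"] * n_rep}, index=counts.columns
        )
        return CountMatrix(counts, meta)

    @pytest.mark.parametrize("method", ["nb_wald", "moderated_t"])
    def test_label_swap_negates_log2fc_and_keeps_p(self, method):
        cm = self._null_counts(seed=4)
        fwd = de_test(cm, "a", "b", method=method)
        rev = de_test(cm, "b", "a", method=method)
        np.testing.assert_allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-10)
        np.testing.assert_allclose(fwd.table["p"], rev.table["p"], atol=1e-10)

    def test_all_zero_gene_is_not_expressed_with_p_one(self):
        cm = self._null_counts(n_genes=20, seed=5)
        cm.counts.iloc[0] = 0
        res = de_test(cm, "a", "b", method="moderated_t")
        row = res.table.iloc[0]
        assert row["status"] == "not_expressed"
        assert row["p"] == 1.0
        assert row["log2fc"] == 0.0

    def test_single_replicate_condition_rejected(self):
        cm = self._null_counts(n_rep=5)
        meta = cm.sample_meta.copy()
        meta.loc[meta.index[0], "condition"] = "lonely"
        cm2 = CountMatrix(cm.counts, meta)
        with pytest.raises(ValueError, match="replicates"):
            de_test(cm2, "lonely", "b")

    def test_planted_log2fc_recovered_with_low_dispersion(self):
        ann = simulate_annotation(150, {"chr1": 1_500_000}, seed=6)
        ids = [g.gene_id for g in ann.genes]
        genes = pd.DataFrame(
            {
                "is_expressed": True,
                "cluster": 0,
                "baseline": 400.0,
                "effect.a": 0.0,
                "effect.b": 2.0,
            },
            index=pd.Index(ids, name="gene_id"),
        )
        truth = SyntheticTruth(genes, ["a", "b"])
        design = pd.DataFrame(
            {"condition": ["a"] * 5 + ["b"] * 5}, index=[f"s{i}" for i in range(10)]
        )
        cm = simulate_counts(ann, truth, design, nb_dispersion=0.005,
                             depth_multiplier_sd=0.05, seed=7)
        res = de_test(cm, "a", "b", method="nb_wald")
        assert res.table["log2fc"].mean() == pytest.approx(2.0, abs=0.2)


class TestCallStatus:
    @staticmethod
    def _result(log2fc, p, fdr=None):
        from polproc.diffexp import ComparisonResult

        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p": p,
                "fdr": fdr if fdr is not None else p,
                "status": ["untested"] * len(p),
            },
            index=pd.Index([f"g{i}" for i in range(len(p))], name="gene_id"),
        )
        return ComparisonResult(table, "a", "b")

    def test_fold_change_two_with_small_p_is_up(self):
        res = call_status(self._result([1.0], [0.04]), fc_threshold=2.0)
        assert res.table["status"].iloc[0] == "up"

    def test_below_fold_threshold_is_unregulated_despite_tiny_p(self):
        res = call_status(self._result([0.9], [0.001]), fc_threshold=2.0)
        assert res.table["status"].iloc[0] == "unregulated"

    def test_down_call_is_symmetric(self):
        res = call_status(self._result([-1.2, 1.2], [0.01, 0.01]), fc_threshold=2.0)
        assert list(res.table["status"]) == ["down", "up"]

    def test_fdr_criterion_switch(self):
        res = call_status(
            self._result([2.0], [0.01], fdr=[0.2]), fc_threshold=2.0, use_fdr=True
        )
        assert res.table["status"].iloc[0] == "unregulated"
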