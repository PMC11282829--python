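import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import gpcrhunt as gh
from conftest import random_counts
from _oracles import filter_keep_brute, tmm_factors_brute


def _cm(arr, cohort="c"):
    arr = np.asarray(arr)
    return gh.CountMatrix(cohort, pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])]))


class TestCpm:
    def test_simple_values(self):
        cpm = gh.compute_cpm(_cm([[10], [0]]))
        assert cpm.values.iloc[0, 0] == 1e6
        assert cpm.values.iloc[1, 0] == 0.0

    def test_matches_hand_arithmetic(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 100, size=(4, 3))
        counts[0] += 1  # avoid zero library
        cpm = gh.compute_cpm(_cm(counts)).values.to_numpy()
        lib = counts.sum(axis=0)
        for g in range(4):
            for k in range(3):
                assert cpm[g, k] == pytest.approx(counts[g, k] / lib[k] * 1e6)

    def test_zero_library_size_names_sample(self):
        with pytest.raises(gh.ValidationError, match="s1"):
            gh.compute_cpm(_cm([[1, 0], [1, 0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.int64, (6, 3), elements=st.integers(0, 1000)))
    def test_columns_sum_to_one_million(self, counts):
        counts[0] += 1
        cpm = gh.compute_cpm(_cm(counts)).values
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)


class TestFilter:
    def test_mostly_zero_gene_discarded(self):
        counts = np.ones((2, 10), dtype=int)
        counts[0, :8] = 0  # zero in 8/10 > 70% of samples
        kept = gh.filter_low_expression(_cm(counts),
                                        gh.FilterConfig(mode="nonzero_fraction"))
        assert kept.gene_symbols.tolist() == ["g1"]

    def test_consistently_expressed_gene_kept(self):
        counts = np.full((2, 10), 50, dtype=int)
        kept = gh.filter_low_expression(_cm(counts),
                                        gh.FilterConfig(mode="cpm_gt1"))
        assert len(kept.gene_symbols) == 2

    @pytest.mark.parametrize("mode", ["nonzero_fraction", "cpm_gt1"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_gene_scan(self, mode, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 5, size=(50, 8))
        counts[:, 0] += 1
        cfg = gh.FilterConfig(mode=mode, sample_fraction=0.5, cpm_threshold=1.0)
        kept = gh.filter_low_expression(_cm(counts), cfg)
        expected = filter_keep_brute(counts, mode, 1.0, 0.5)
        assert kept.gene_symbols.tolist() == [f"g{i}" for i in expected]

    def test_gene_order_and_counts_preserved(self):
        counts = np.array([[5, 5], [0, 0], [3, 3]])
        kept = gh.filter_low_expression(_cm(counts))
        assert kept.gene_symbols.tolist() == ["g0", "g2"]
        assert kept.counts.loc["g2"].tolist() == [3, 3]

    def test_all_genes_removed_is_an_error(self):
        with pytest.raises(gh.ValidationError, match="threshold"):
            gh.filter_low_expression(
                _cm([[1, 1, 1], [2, 2, 2]]),
                gh.FilterConfig(mode="cpm_gt1", cpm_threshold=1e9))

    @pytest.mark.parametrize("seed", range(5))
    def test_tightening_thresholds_never_grows_kept_set(self, seed):
        cm = random_counts(seed, n_genes=40, n_samples=10)
        base = set(gh.filter_low_expression(
            cm, gh.FilterConfig(mode="cpm_gt1", cpm_threshold=1.0,
                                sample_fraction=0.3)).gene_symbols)
        for thr, frac in [(5.0, 0.3), (1.0, 0.6), (5.0, 0.6)]:
            try:
                tight = set(gh.filter_low_expression(
                    cm, gh.FilterConfig(mode="cpm_gt1", cpm_threshold=thr,
                                        sample_fraction=frac)).gene_symbols)
            except gh.ValidationError:
                tight = set()
            assert tight <= base


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5]]), (1, 2))
        nf = gh.tmm_factors(_cm(counts))
        assert nf.tmm_factor.tolist() == [1.0, 1.0]

    def test_scalar_scaled_column_gives_unit_factors(self):
        a = np.array([7, 13, 2, 40, 9])
        counts = np.stack([a, 3 * a], axis=1)
        nf = gh.tmm_factors(_cm(counts))
        # proportions unchanged: scaling absorbed entirely by library size
        assert nf.tmm_factor.tolist() == [1.0, 1.0]
        assert nf.effective_library_size.tolist() == [71.0, 213.0]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_transcription(self, seed):
        cm = random_counts(seed, n_genes=20, n_samples=4)
        ours = gh.tmm_factors(cm).tmm_factor.to_numpy()
        brute = tmm_factors_brute(cm.counts.to_numpy())
        np.testing.assert_allclose(ours, brute, atol=1e-10, rtol=0)

    def test_unweighted_variant_matches_brute_force(self):
        cm = random_counts(99, n_genes=30, n_samples=5)
        cfg = gh.TmmConfig(weighting=False)
        ours = gh.tmm_factors(cm, cfg).tmm_factor.to_numpy()
        brute = tmm_factors_brute(cm.counts.to_numpy(), weighting=False)
        np.testing.assert_allclose(ours, brute, atol=1e-10, rtol=0)

    def test_geometric_mean_is_one(self):
        for seed in range(5):
            f = gh.tmm_factors(random_counts(seed, 25, 6)).tmm_factor
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_gene_permutation_invariance(self):
        cm = random_counts(3, 30, 4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        shuffled = gh.CountMatrix("c", cm.counts.iloc[perm])
        np.testing.assert_allclose(gh.tmm_factors(cm).tmm_factor,
                                   gh.tmm_factors(shuffled).tmm_factor,
                                   atol=1e-12)

    def test_requires_two_samples(self):
        with pytest.raises(gh.ValidationError, match="2 samples"):
            gh.tmm_factors(_cm([[5], [3]]))

    def test_matches_edger_reference_implementation(self, tmp_path):
        # independent cross-check against the canonical R implementation
        import subprocess
        cm = random_counts(7, n_genes=200, n_samples=4)
        p = tmp_path / "counts.tsv"
        cm.counts.to_csv(p, sep="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'y <- as.matrix(read.delim("{p}", row.names=1));'
             'cat(sprintf("%.10f", calcNormFactors(y, method="TMM")), sep="\\n")'],
            capture_output=True, text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        theirs = np.array([float(x) for x in r.stdout.split()])
        ours = gh.tmm_factors(cm).tmm_factor.to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestRpkm:
    def _ann(self, genes, lengths):
        return gh.GeneAnnotation(pd.DataFrame(
            {"length_bp": lengths, "is_gpcr": False},
            index=pd.Index(genes, name="symbol")))

    def _nf(self, samples, eff):
        eff = pd.Series(eff, index=samples, dtype=float)
        return gh.NormalizationFactors(sample_ids=list(samples),
                                       library_size=eff,
                                       tmm_factor=pd.Series(1.0, index=samples))

    def test_reference_value(self):
        cm = _cm([[10]])
        rpkm = gh.compute_rpkm(cm, self._ann(["g0"], [1000]),
                               self._nf(["s0"], [1e6]))
        assert rpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_doubling_length_halves_rpkm(self):
        cm = _cm([[10]])
        nf = self._nf(["s0"], [1e6])
        r1 = gh.compute_rpkm(cm, self._ann(["g0"], [1000]), nf).values.iloc[0, 0]
        r2 = gh.compute_rpkm(cm, self._ann(["g0"], [2000]), nf).values.iloc[0, 0]
        assert r2 == pytest.approx(r1 / 2)

    def test_matches_hand_arithmetic_with_nonunit_factors(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 50, size=(5, 3))
        lengths = [500, 1000, 1500, 2000, 800]
        cm = _cm(counts)
        nf = gh.NormalizationFactors(
            sample_ids=list(cm.sample_ids),
            library_size=cm.library_sizes.astype(float),
            tmm_factor=pd.Series([0.9, 1.0, 1.25], index=cm.sample_ids))
        rpkm = gh.compute_rpkm(cm, self._ann(cm.gene_symbols, lengths), nf)
        eff = cm.library_sizes.to_numpy() * np.array([0.9, 1.0, 1.25])
        for g in range(5):
            for k in range(3):
                assert rpkm.values.iloc[g, k] == pytest.approx(
                    counts[g, k] * 1e9 / (lengths[g] * eff[k]))

    def test_scaling_counts_scales_rpkm_linearly(self):
        counts = np.array([[4, 8], [6, 2]])
        ann = self._ann(["g0", "g1"], [1000, 1000])
        nf = self._nf(["s0", "s1"], [1e6, 1e6])
        r1 = gh.compute_rpkm(_cm(counts), ann, nf).values.to_numpy()
        r3 = gh.compute_rpkm(_cm(3 * counts), ann, nf).values.to_numpy()
        np.testing.assert_allclose(r3, 3 * r1)

    def test_missing_gene_length_listed(self):
        cm = _cm([[1], [1]])
        ann = self._ann(["g0"], [1000])
        with pytest.raises(gh.ValidationError, match="g1"):
            gh.compute_rpkm(cm, ann, self._nf(["s0"], [1e6]))


class TestDistributionSummary:
    def test_constant_matrix_has_equal_quantiles(self):
        e = gh.ExpressionMatrix(pd.DataFrame(np.full((3, 4), 7.0)), "RPKM")
        q = gh.distribution_summary(e)["all"]["quantiles"]
        assert len(set(q.values())) == 1

    def test_full_subset_equals_global(self):
        e = gh.ExpressionMatrix(
            pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4),
                         index=["a", "b", "c"]), "RPKM")
        s = gh.distribution_summary(e, gene_subset=["a", "b", "c"])
        assert s["subset"] == s["all"]

    def test_empty_subset_warns(self, caplog):
        e = gh.ExpressionMatrix(pd.DataFrame(np.ones((2, 2))), "RPKM")
        with caplog.at_level("WARNING", logger="gpcrhunt"):
            s = gh.distribution_summary(e, gene_subset=["nope"])
        assert s["subset"]["n_genes"] == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_receptor_family_sits_below_global_median(self, default_collection):
        # mirrors the observed low-to-moderate receptor expression bias
        coll = default_collection
        cid = coll.cancer_cohort_ids[0]
        cm = gh.filter_low_expression(coll.cohorts[cid])
        nf = gh.tmm_factors(cm)
        rpkm = gh.compute_rpkm(cm, coll.annotation, nf)
        s = gh.distribution_summary(rpkm, coll.annotation.gpcr_symbols)
        assert s["subset"]["quantiles"][50] < s["all"]["quantiles"][50]
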