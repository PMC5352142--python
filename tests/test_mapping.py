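"""QC filters, normalization, Spearman scans, permutation FDR, LD utilities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pairedqtl import mapping, simulate
from pairedqtl.mapping import FilterThresholds, NoSnpsRetainedError

from conftest import make_expression, make_genotypes


class TestFilterSnps:
    @staticmethod
    def _hwe_column(rng, n=100, maf=0.3):
        return rng.binomial(1, maf, n) + rng.binomial(1, maf, n).astype(float)

    def test_monomorphic_snp_removed_as_maf(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(np.column_stack([np.zeros(100), self._hwe_column(rng)]))
        res = mapping.filter_snps(g)
        log = res.log.set_index("snp_id")
        assert log.loc["v0", "reason"] == "maf"
        assert "v0" not in res.genotypes.snp_ids
        assert "v1" in res.genotypes.snp_ids

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(0)
        d = np.column_stack([self._hwe_column(rng), self._hwe_column(rng)])
        d[:10, 0] = np.nan  # 10% missing at threshold 0.95
        g = make_genotypes(d)
        res = mapping.filter_snps(g)
        assert res.log.set_index("snp_id").loc["v0", "reason"] == "call_rate"

    def test_all_heterozygote_removed_as_hwe(self):
        d = np.column_stack([np.ones(100), np.repeat([0, 1, 2], [25, 50, 25])[:100]])
        g = make_genotypes(d)
        res = mapping.filter_snps(g)
        assert res.log.set_index("snp_id").loc["v0", "reason"] == "hwe"
        # sanity on the chi-square scale: expected 25/50/25 vs observed 0/100/0
        assert mapping.hwe_pvalue(d[:, 0]) < 1e-20

    def test_soft_dosages_skip_hwe(self):
        rng = np.random.default_rng(1)
        d = np.full((100, 2), 1.0)
        d[:, 0] += rng.uniform(-0.4, 0.4, 100)  # imputed-looking, non-integer
        g = make_genotypes(np.clip(d, 0, 2))
        res = mapping.filter_snps(g)
        log = res.log.set_index("snp_id")
        assert log.loc["v0", "reason"] == "hwe_skipped_soft_dosages"
        assert log.loc["v0", "status"] == "kept"

    def test_all_removed_raises(self):
        g = make_genotypes(np.zeros((20, 3)))
        with pytest.raises(NoSnpsRetainedError):
            mapping.filter_snps(g)


class TestQuantileNormalize:
    def test_identical_multisets_are_fixed_point_up_to_log(self):
        v = np.array([[1.0, 4.0, 2.0], [2.0, 1.0, 4.0]])
        out = mapping.quantile_normalize_log2(make_expression(v)).values.to_numpy()
        assert np.allclose(out, np.log2(v))

    def test_three_by_three_matches_hand_computed_order_statistics(self):
        v = np.array([[2.0, 8.0, 4.0], [1.0, 16.0, 2.0], [32.0, 2.0, 8.0]])
        # order-statistic means: sorted rows (2,4,8), (1,2,16), (2,8,32) -> (5/3, 14/3, 56/3)
        ref = np.array([5 / 3, 14 / 3, 56 / 3])
        out = mapping.quantile_normalize_log2(make_expression(v)).values.to_numpy()
        expected = np.log2(
            np.array(
                [
                    [ref[0], ref[2], ref[1]],
                    [ref[0], ref[2], ref[1]],
                    [ref[2], ref[0], ref[1]],
                ]
            )
        )
        assert np.allclose(out, expected)

    def test_every_sample_same_multiset_after(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(size=(5, 40))
        out = mapping.quantile_normalize_log2(make_expression(v)).values.to_numpy()
        ref = np.sort(out[0])
        for row in out[1:]:
            assert np.allclose(np.sort(row), ref)

    def test_ties_get_mean_of_span(self):
        v = np.array([[1.0, 1.0, 4.0], [1.0, 2.0, 4.0]])
        out = mapping.quantile_normalize_log2(make_expression(v)).values.to_numpy()
        assert np.isclose(out[0, 0], out[0, 1])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mapping.quantile_normalize_log2(make_expression(np.array([[0.0, 1.0]])))


class TestResidualize:
    def test_intercept_only_mean_centres(self):
        v = np.random.default_rng(0).normal(2.0, 1.0, (30, 4))
        out = mapping.residualize(make_expression(v)).values.to_numpy()
        assert np.allclose(out, v - v.mean(axis=0))

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"x": rng.normal(size=25)}, index=[f"S{i}" for i in range(25)])
        expr = make_expression(cov[["x"]].to_numpy())
        out = mapping.residualize(expr, cov).values.to_numpy()
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 5))
        C = rng.normal(size=(20, 3))
        cov = pd.DataFrame(C, columns=list("abc"), index=[f"S{i}" for i in range(20)])
        out = mapping.residualize(make_expression(Y), cov).values.to_numpy()
        X = np.column_stack([np.ones(20), C])
        oracle = Y - X @ np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(out, oracle, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 3))
        cov = pd.DataFrame(
            rng.normal(size=(40, 2)), columns=["u", "v"], index=[f"S{i}" for i in range(40)]
        )
        out = mapping.residualize(make_expression(Y), cov).values.to_numpy()
        for j in range(3):
            for c in cov.columns:
                assert abs(np.corrcoef(out[:, j], cov[c])[0, 1]) < 1e-8

    def test_collinear_covariates_named(self):
        cov = pd.DataFrame(
            {"a": np.arange(10.0), "b": 2 * np.arange(10.0)},
            index=[f"S{i}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="b"):
            mapping.residualize(make_expression(np.random.default_rng(0).normal(size=(10, 2))), cov)


class TestCisTransWindows:
    def test_perfect_monotone_gives_rho_one(self):
        d = np.arange(6.0)[:, None] / 3.0  # strictly increasing dosage-like values
        g = make_genotypes(d / d.max() * 2)
        e = make_expression(d * 3.0, midpoints=[1000])
        recs = mapping.map_cis(g, e)
        assert np.isclose(recs["rho"].iloc[0], 1.0)

    def test_cis_window_boundary_inclusive(self):
        g = make_genotypes(np.random.default_rng(0).integers(0, 3, (30, 2)).astype(float),
                           positions=[1_001_000, 1_001_001])
        e = make_expression(np.random.default_rng(1).normal(size=(30, 1)), midpoints=[1000])
        recs = mapping.map_cis(g, e, window_bp=1_000_000)
        # SNP at exactly 1 Mb tested; 1 Mb + 1 bp not
        assert set(recs["snp_id"]) == {"v0"}

    def test_spearman_matches_brute_force_midranks(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.2, 0.8, 2.1, 1.9, 3.0, 2.7])
        g = make_genotypes(x[:, None])
        e = make_expression(y[:, None], midpoints=[1000])
        recs = mapping.map_cis(g, e)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert np.isclose(recs["rho"].iloc[0], oracle, atol=1e-12)
        assert np.isclose(recs["rho"].iloc[0], stats.spearmanr(x, y).statistic, atol=1e-12)

    def test_trans_distance_rule(self):
        rng = np.random.default_rng(5)
        g = make_genotypes(rng.integers(0, 3, (30, 2)).astype(float),
                           positions=[1_000, 10_000_000])
        e = make_expression(rng.normal(size=(30, 2)), midpoints=[4_000_000, 4_000_001])
        # SNP v0 at 1 kb: ~4 Mb from both probes -> excluded (<= 5 Mb)
        # SNP v1 at 10 Mb: ~6 Mb away -> tested
        recs = mapping.map_trans(g, e, ["v0", "v1"])
        assert set(recs["snp_id"]) == {"v1"}

    def test_trans_different_chromosome_always_tested(self):
        rng = np.random.default_rng(6)
        g = make_genotypes(rng.integers(0, 3, (30, 1)).astype(float), chrom="chr1")
        e = make_expression(rng.normal(size=(30, 1)), chrom="chr2", midpoints=[1500])
        recs = mapping.map_trans(g, e, ["v0"])
        assert len(recs) == 1

    def test_missing_subset_id_raises(self):
        g = make_genotypes(np.ones((10, 1)) * 1.0)
        e = make_expression(np.random.default_rng(0).normal(size=(10, 1)))
        with pytest.raises(KeyError, match="nope"):
            mapping.map_trans(g, e, ["nope"])

    def test_result_independent_of_input_order(self, small_cohort, residualized):
        eA, _ = residualized
        g = small_cohort.genotypes
        recs = mapping.map_cis(g, eA)
        shuffled = g.subset_snps(list(g.snp_ids[::-1]))
        recs2 = mapping.map_cis(shuffled, eA)
        pd.testing.assert_frame_equal(recs, recs2)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rho_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30)
        g = make_genotypes(x[:, None])
        recs1 = mapping.map_cis(g, make_expression(y[:, None], midpoints=[1000]))
        recs2 = mapping.map_cis(g, make_expression(np.exp(y)[:, None], midpoints=[1000]))
        assert np.isclose(recs1["rho"].iloc[0], recs2["rho"].iloc[0], atol=1e-12)


class TestCorrectCisEffects:
    def test_probe_without_hit_passes_through(self, small_cohort, residualized):
        eA, _ = residualized
        hits = pd.DataFrame(
            {"snp_id": ["snp00005"], "probe_id": ["probe0001"], "p_nominal": [1e-10],
             "q_value": [0.0], "n_used": [300], "rho": [0.5], "scope": ["cis"]}
        )
        out = mapping.correct_cis_effects(eA, small_cohort.genotypes, hits)
        untouched = [p for p in eA.probe_ids if p != "probe0001"]
        pd.testing.assert_frame_equal(out.values[untouched], eA.values[untouched])

    def test_corrected_probe_orthogonal_to_top_snp(self, small_cohort, residualized):
        eA, _ = residualized
        hits = pd.DataFrame(
            {"snp_id": ["snp00005"], "probe_id": ["probe0001"], "p_nominal": [1e-10],
             "q_value": [0.0], "n_used": [300], "rho": [0.5], "scope": ["cis"]}
        )
        out = mapping.correct_cis_effects(eA, small_cohort.genotypes, hits)
        r = np.corrcoef(
            out.values["probe0001"], small_cohort.genotypes.dosages["snp00005"]
        )[0, 1]
        assert abs(r) < 1e-12

    def test_cis_driven_probe_loses_signal_after_correction(self):
        arch = simulate.EqtlArchitecture(
            n_samples=500, n_snps=20, n_probes=4, seed=31,
            cis_effects=((10, 2, 1.0, 1.0),), covariate_effect_sd=0.0,
        )
        co = simulate.simulate_cohort(arch)
        eA = mapping.residualize(co.expression_cellA, co.covariates)
        hits = pd.DataFrame(
            {"snp_id": ["snp00010"], "probe_id": ["probe0002"], "p_nominal": [1e-20],
             "q_value": [0.0], "n_used": [500], "rho": [0.7], "scope": ["cis"]}
        )
        out = mapping.correct_cis_effects(eA, co.genotypes, hits)
        rho = stats.spearmanr(
            out.values["probe0002"], co.genotypes.dosages["snp00010"]
        ).statistic
        assert abs(rho) < 0.05


class TestProbeLevelFdr:
    def test_rejects_too_few_permutations(self, small_cohort, residualized):
        eA, _ = residualized
        recs = mapping.map_cis(small_cohort.genotypes, eA)
        with pytest.raises(ValueError):
            mapping.probe_level_fdr(recs, small_cohort.genotypes, eA, n_permutations=5)

    def test_single_pair_q_close_to_exact_permutation_p(self):
        x = np.array([0, 1, 2, 0, 1], dtype=float)
        y = np.array([0.3, 1.1, 2.4, 0.1, 0.8])
        g = make_genotypes(x[:, None])
        e = make_expression(y[:, None], midpoints=[1000])
        recs = mapping.map_cis(g, e)
        out = mapping.probe_level_fdr(recs, g, e, n_permutations=4000, seed=0)
        exact = mapping.spearman_exact_p(x, y)
        # the t-approximation p thresholds the permutation null of the same
        # statistic, so the count-ratio estimate converges to the exact
        # enumeration p for a single probe/SNP
        assert abs(out["q_value"].iloc[0] - exact) < 0.05

    def test_q_values_stay_in_unit_interval_on_null_data(self):
        rng = np.random.default_rng(8)
        # null data: the count ratio can exceed 1 before capping; q must not
        g = make_genotypes(rng.integers(0, 3, (40, 3)).astype(float))
        e = make_expression(rng.normal(size=(40, 2)), midpoints=[1000, 2000])
        recs = mapping.map_cis(g, e)
        out = mapping.probe_level_fdr(recs, g, e, n_permutations=50, seed=1)
        assert (out["q_value"] <= 1.0).all() and (out["q_value"] >= 0.0).all()

    def test_q_monotone_in_observed_min_p(self, small_cohort, residualized):
        eA, _ = residualized
        recs = mapping.map_cis(small_cohort.genotypes, eA)
        out = mapping.probe_level_fdr(
            recs, small_cohort.genotypes, eA, n_permutations=50, seed=2
        )
        per_probe = out.groupby("probe_id").agg(
            minp=("p_nominal", "min"), q=("q_value", "first")
        ).sort_values("minp")
        assert (per_probe["q"].diff().dropna() >= -1e-12).all()

    def test_true_effects_detected_at_low_q(self, small_cohort, residualized):
        eA, _ = residualized
        recs = mapping.map_cis(small_cohort.genotypes, eA)
        out = mapping.probe_level_fdr(
            recs, small_cohort.genotypes, eA, n_permutations=100, seed=3
        )
        sig_probes = set(out.loc[out["q_value"] <= 0.05, "probe_id"])
        assert {"probe0001", "probe0008", "probe0014"} <= sig_probes


class TestPairwiseR2:
    def test_self_r2_is_one_and_independent_snps_near_zero(self):
        g = simulate.simulate_genotypes(10000, [0.3, 0.4], seed=21)
        r2 = mapping.pairwise_r2(g, list(g.snp_ids))
        assert r2.iloc[0, 0] == 1.0
        assert r2.iloc[0, 1] < 0.01

    def test_duplicated_column_matches_pearson_squared_oracle(self):
        rng = np.random.default_rng(22)
        x = rng.integers(0, 3, 100).astype(float)
        y = x.copy()
        y[0] = 2.0 - y[0]  # flip one genotype
        g = make_genotypes(np.column_stack([x, y]))
        r2 = mapping.pairwise_r2(g, ["v0", "v1"])
        oracle = np.corrcoef(x, y)[0, 1] ** 2
        assert np.isclose(r2.loc["v0", "v1"], oracle, atol=1e-12)

    def test_zero_variance_snp_flagged_undefined(self):
        g = make_genotypes(np.column_stack([np.ones(30), np.arange(30) % 3]).astype(float))
        r2 = mapping.pairwise_r2(g, ["v0", "v1"])
        assert np.isnan(r2.loc["v0", "v1"]) and np.isnan(r2.loc["v0", "v0"])
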