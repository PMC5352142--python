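"""Configuration Bayes factors, hierarchical EM and model-averaged posteriors."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairedqtl import bma, mapping, simulate
from pairedqtl.bma import BmaGrid, CONFIGURATIONS


def stat_row(bA, seA, bB, seB):
    return pd.Series(
        {"snp_id": "s", "probe_id": "p", "betaA": bA, "seA": seA, "betaB": bB, "seB": seB}
    )


class TestConfigurationBf:
    def test_null_effects_have_bf_at_most_one(self):
        bf = bma.configuration_bf(stat_row(0.0, 0.2, 0.0, 0.3), bma.default_grid())
        for gamma in CONFIGURATIONS:
            assert bf[gamma] <= 0.0  # log scale

    def test_single_tissue_matches_univariate_closed_form(self):
        phi2, omega2 = 0.03, 0.01
        grid = BmaGrid(points=((phi2, omega2),))
        beta, se = 0.5, 0.12
        bf = bma.configuration_bf(stat_row(beta, se, 0.0, 1.0), grid)
        W = phi2 + omega2
        z2 = (beta / se) ** 2
        closed = np.sqrt(se**2 / (se**2 + W)) * np.exp(z2 * W / (2 * (se**2 + W)))
        assert abs(bf[("A",)] - np.log(closed)) < 1e-10

    def test_concordant_strong_effects_favor_shared_configuration(self):
        bf = bma.configuration_bf(stat_row(0.6, 0.1, 0.6, 0.1), bma.default_grid())
        assert bf[("A", "B")] > bf[("A",)] and bf[("A", "B")] > bf[("B",)]

    def test_vectorized_table_matches_generic_implementation(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(50)],
                "probe_id": ["p"] * 50,
                "betaA": rng.normal(0, 0.5, 50),
                "seA": rng.uniform(0.05, 0.4, 50),
                "betaB": rng.normal(0, 0.5, 50),
                "seB": rng.uniform(0.05, 0.4, 50),
            }
        )
        grid = bma.default_grid()
        table = bma.log_bf_table(frame, grid)
        for i in (0, 13, 49):
            ref = bma.configuration_bf(frame.iloc[i], grid)
            assert abs(table["logbf_A"].iloc[i] - ref[("A",)]) < 1e-10
            assert abs(table["logbf_B"].iloc[i] - ref[("B",)]) < 1e-10
            assert abs(table["logbf_AB"].iloc[i] - ref[("A", "B")]) < 1e-10


class TestSummaryStats:
    def test_perfect_fit_triggers_se_floor(self):
        g = simulate.simulate_genotypes(50, [0.4], seed=2)
        vals = 2.0 * g.dosages.to_numpy()
        from conftest import make_expression

        e = make_expression(vals, midpoints=[1000])
        e.values.index = g.samples
        pairs = pd.DataFrame({"snp_id": ["snp00000"], "probe_id": ["pr0"]})
        st_ = bma.compute_summary_stats(g, e, e, pairs)
        assert np.isclose(st_["betaA"].iloc[0], 2.0)
        assert st_["seA"].iloc[0] == bma.SE_FLOOR

    def test_null_z_scores_standard_normal(self):
        rng = np.random.default_rng(3)
        n, m = 200, 2000
        x = rng.binomial(2, 0.3, (n, 1)).astype(float)
        zs = []
        for j in range(m):
            y = rng.normal(size=n)
            xc = x[:, 0] - x[:, 0].mean()
            beta = xc @ y / (xc @ xc)
            resid = y - y.mean() - beta * xc
            se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
            zs.append(beta / se)
        assert stats.kstest(zs, "norm").pvalue > 0.01


class TestEmFit:
    @staticmethod
    def _table(logbfs):
        rows = []
        for i, (a, b, ab) in enumerate(logbfs):
            rows.append(
                {"snp_id": f"s{i}", "probe_id": f"p{i}", "logbf_A": a, "logbf_B": b, "logbf_AB": ab}
            )
        return pd.DataFrame(rows)

    def test_flat_bfs_keep_eta_at_init_and_flag(self):
        tab = self._table([(1.0, 1.0, 1.0)] * 20)
        init = {("A",): 0.5, ("B",): 0.3, ("A", "B"): 0.2}
        fit = bma.em_fit(tab, pi0=0.5, init_eta=init)
        assert fit.flat_likelihood
        for g in CONFIGURATIONS:
            assert abs(fit.eta[g] - init[g]) < 1e-9

    def test_single_allowed_configuration_degenerates_immediately(self):
        tab = self._table([(0.5, 1.5, 2.5)] * 10)
        fit = bma.em_fit(tab, pi0=0.3, allowed_configs=[("A", "B")])
        assert fit.eta[("A", "B")] == 1.0

    def test_loglik_trace_nondecreasing_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            tab = self._table(rng.normal(0, 3, size=(15, 3)))
            fit = bma.em_fit(tab, pi0=rng.uniform(0.1, 0.9))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_shared_effect_simulation_recovers_eta_both(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            beta = rng.normal(0, 0.4)
            for j in range(3):
                b1 = beta + rng.normal(0, 0.05)
                rows.append(
                    {
                        "snp_id": f"s{j}",
                        "probe_id": f"p{i}",
                        "betaA": b1 if j == 0 else rng.normal(0, 0.05),
                        "seA": 0.05,
                        "betaB": b1 if j == 0 else rng.normal(0, 0.05),
                        "seB": 0.05,
                    }
                )
        tab = bma.log_bf_table(pd.DataFrame(rows))
        fit = bma.em_fit(tab, pi0=0.0)
        assert fit.eta[("A", "B")] >= 0.8


class TestProbePosteriors:
    def test_uninformative_bfs_give_one_minus_pi0(self):
        tab = TestEmFit._table([(0.0, 0.0, 0.0)] * 5)
        fit = bma.em_fit(tab, pi0=0.35)
        post = bma.probe_posteriors(tab, fit)
        assert np.allclose(post["posterior_has_eqtl"], 0.65, atol=1e-10)

    def test_pi0_one_kills_all_posteriors(self):
        tab = TestEmFit._table([(2.0, 1.0, 3.0)] * 5)
        fit = bma.em_fit(tab, pi0=1.0)
        post = bma.probe_posteriors(tab, fit)
        assert (post["posterior_has_eqtl"] == 0.0).all()

    def test_best_snp_posterior_normalization(self):
        # two SNPs with BMA BFs 9 and 1 -> best-SNP posterior 0.9
        tab = pd.DataFrame(
            {
                "snp_id": ["s1", "s2"],
                "probe_id": ["p", "p"],
                "logbf_A": np.log([9.0, 1.0]),
                "logbf_B": np.log([9.0, 1.0]),
                "logbf_AB": np.log([9.0, 1.0]),
            }
        )
        fit = bma.em_fit(tab, pi0=0.5)
        post = bma.probe_posteriors(tab, fit)
        assert post["best_snp_id"].iloc[0] == "s1"
        assert abs(post["posterior_best_snp"].iloc[0] - 0.9) < 1e-12

    def test_configuration_split_sums_to_has_eqtl(self):
        rng = np.random.default_rng(6)
        tab = TestEmFit._table(rng.normal(0, 2, size=(30, 3)))
        fit = bma.em_fit(tab, pi0=0.4)
        post = bma.probe_posteriors(tab, fit)
        total = post[["posterior_A", "posterior_B", "posterior_AB"]].sum(axis=1)
        assert np.allclose(total, post["posterior_has_eqtl"], atol=1e-12)


class TestPi0Permutation:
    def test_null_cohort_pi0_near_one(self):
        arch = simulate.EqtlArchitecture(n_samples=150, n_snps=80, n_probes=120, seed=7)
        co = simulate.simulate_cohort(arch)
        eA = mapping.residualize(co.expression_cellA, co.covariates)
        eB = mapping.residualize(co.expression_cellB, co.covariates)
        res = bma.estimate_pi0_perm(co.genotypes, eA, eB, n_permutations=300, seed=8)
        assert res.pi0 >= 0.9

    def test_deterministic_given_seed(self):
        arch = simulate.EqtlArchitecture(n_samples=60, n_snps=30, n_probes=20, seed=9)
        co = simulate.simulate_cohort(arch)
        eA = mapping.residualize(co.expression_cellA, co.covariates)
        eB = mapping.residualize(co.expression_cellB, co.covariates)
        a = bma.estimate_pi0_perm(co.genotypes, eA, eB, n_permutations=20, seed=10)
        b = bma.estimate_pi0_perm(co.genotypes, eA, eB, n_permutations=20, seed=10)
        assert a.pi0 == b.pi0

    def test_partially_active_cohort_recovers_pi0(self):
        # the tail-based estimator needs many probes and permutations before
        # its sampling noise (inflated by permutation reuse across probes)
        # and the discrete (1 + c)/(1 + B) offset allow +-0.1 recovery
        arch = simulate.EqtlArchitecture(
            n_samples=250, n_snps=30, n_probes=1000, seed=11,
            maf_range=(0.2, 0.5),
            cis_effects=tuple((k % 30, k, 1.0, 1.0) for k in range(300)),
        )
        co = simulate.simulate_cohort(arch)
        eA = mapping.residualize(co.expression_cellA, co.covariates)
        eB = mapping.residualize(co.expression_cellB, co.covariates)
        res = bma.estimate_pi0_perm(co.genotypes, eA, eB, n_permutations=1000, seed=12)
        assert abs(res.pi0 - 0.7) < 0.1
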