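"""Generator: LD structure, planted co-expression, causal outcome path."""

import numpy as np
import pytest
from scipy import stats

from fetomod.synthetic import (SimulationParams, genetic_module_activity,
                               make_two_sample_stats, simulate_cohort,
                               simulate_genotypes, simulate_outcome)


class TestGenotypes:
    def test_seed_reproducibility(self):
        a = simulate_genotypes(50, 40, 10, 0.5, (0.1, 0.5), seed=9)
        b = simulate_genotypes(50, 40, 10, 0.5, (0.1, 0.5), seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants == b.variants

    def test_rho_zero_independence(self):
        g = simulate_genotypes(2000, 40, 10, 0.0, (0.2, 0.4), seed=1)
        c = np.corrcoef(g.dosages.T) ** 2
        iu = np.triu_indices(40, 1)
        assert c[iu].mean() < 0.01

    def test_block_structure(self):
        g = simulate_genotypes(2000, 40, 10, 0.9, (0.25, 0.35), seed=2)
        r2 = np.corrcoef(g.dosages.T) ** 2
        block = np.repeat(np.arange(4), 10)
        same = block[:, None] == block[None, :]
        iu = np.triu_indices(40, 1)
        within = r2[iu][same[iu]].mean()
        between = r2[iu][~same[iu]].mean()
        assert within > 5 * between

    def test_positions_consecutive_within_block(self):
        g = simulate_genotypes(5, 25, 10, 0.5, (0.1, 0.5), seed=3)
        pos = np.array([v.pos for v in g.variants])
        assert np.all(np.diff(pos[:10]) == 1000)      # inside block
        assert pos[10] - pos[9] > 250_000             # across blocks

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, 5, 1.0, (0.1, 0.5), seed=0)


class TestCohort:
    def test_pure_noise_when_structure_off(self):
        p = SimulationParams(seed=0, n_genes=100, module_sizes=(30,),
                             loading_range=(0.0, 0.0), eqtl_frac=0.0,
                             n_exposure_samples=300, n_snps=50)
        _, expr, _ = simulate_cohort(p)
        c = np.corrcoef(expr.values)
        iu = np.triu_indices(100, 1)
        assert np.abs(c[iu]).mean() < 0.1

    def test_within_module_correlation_matches_closed_form(self, small_cohort):
        """Under the factor model cor(g, g') = ll'/sqrt((l^2+v)(l'^2+v))."""
        params, geno, expr, truth = small_cohort
        genes = [g for g in truth.module_genes("cyan")
                 if g not in truth.eqtl_snp_of_gene][:12]
        idx = [expr.gene_ids.index(g) for g in genes]
        emp = np.corrcoef(expr.values[idx])
        lam = np.array([truth.loadings[g] for g in genes])
        v = params.noise_sd ** 2
        theory = np.outer(lam, lam) / np.sqrt(
            np.outer(lam ** 2 + v, lam ** 2 + v))
        iu = np.triu_indices(len(genes), 1)
        # empirical pairwise correlations carry ~1/sqrt(n) noise, so demand
        # agreement in level and a positive trend, not a tight match
        assert abs(emp[iu].mean() - theory[iu].mean()) < 0.1
        assert np.corrcoef(emp[iu], theory[iu])[0, 1] > 0.2

    def test_between_module_correlation_lower_than_within(self, small_cohort):
        _, _, expr, truth = small_cohort
        c = np.abs(np.corrcoef(expr.values))
        lab = np.array([truth.module_of_gene[g] for g in expr.gene_ids])
        cyan, blue = lab == "cyan", lab == "blue"
        within = c[np.ix_(cyan, cyan)][np.triu_indices(cyan.sum(), 1)].mean()
        between = c[np.ix_(cyan, blue)].mean()
        assert within > 3 * between

    def test_eqtl_recovered_by_ols(self, small_cohort):
        params, geno, expr, truth = small_cohort
        gene, snp = next(iter(truth.eqtl_snp_of_gene.items()))
        d = geno.column(snp)
        y = expr.values[expr.gene_ids.index(gene)]
        slope, _, _, _, se = stats.linregress(d, y)[:5]
        assert abs(slope - truth.eqtl_beta[snp]) < 2.5 * se

    def test_truth_reuse_gives_same_structure_fresh_samples(self, small_cohort):
        params, geno, expr, truth = small_cohort
        rng = np.random.default_rng(123)
        geno2, expr2, truth2 = simulate_cohort(params, rng, "rep", truth=truth)
        assert truth2.module_of_gene == truth.module_of_gene
        assert truth2.eqtl_beta == truth.eqtl_beta
        assert not np.allclose(expr2.values, expr.values)


class TestOutcome:
    def _two_cohorts(self, gamma, seed=5, n=800):
        p = SimulationParams(seed=seed, n_genes=80, module_sizes=(15,),
                             n_snps=200, eqtl_frac=1.0, eqtl_beta_sd=2.0,
                             n_exposure_samples=n, n_outcome_samples=n,
                             gamma=gamma)
        rng = np.random.default_rng(seed)
        ge, ee, truth = simulate_cohort(p, rng, "exp")
        go, _, _ = simulate_cohort(p, rng, "out", n_samples=n, truth=truth)
        y = simulate_outcome(truth, go, p, rng)
        return p, ge, ee, go, y, truth

    def test_seed_determinism(self):
        _, _, _, _, y1, _ = self._two_cohorts(-0.3, seed=11)
        _, _, _, _, y2, _ = self._two_cohorts(-0.3, seed=11)
        np.testing.assert_array_equal(y1, y2)

    def test_null_gamma_gives_null_snp_associations(self):
        p, ge, ee, go, y, truth = self._two_cohorts(0.0, seed=6, n=500)
        pvals = []
        for j in range(go.dosages.shape[1]):
            d = go.dosages[:, j]
            if d.std() == 0:
                continue
            pvals.append(stats.linregress(d, y).pvalue)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.01 < rate < 0.10

    def test_outcome_betas_proportional_to_exposure_betas(self):
        """Slope of outcome on exposure instrument effects recovers gamma."""
        errs = []
        for seed in range(5):
            p, ge, ee, go, y, truth = self._two_cohorts(-0.4, seed=20 + seed,
                                                        n=2000)
            exp, out = make_two_sample_stats(
                ee, ge, y, go, truth.instrument_snps(),
                truth.module_genes("cyan"))
            be = np.array([r.beta for r in exp])
            bo = np.array([r.beta for r in out])
            errs.append(np.polyfit(be, bo, 1)[0])
        assert abs(np.mean(errs) - (-0.4)) < 0.12

    def test_binary_outcome_prevalence(self):
        p = SimulationParams(seed=9, n_genes=50, module_sizes=(10,),
                             n_snps=50, eqtl_frac=1.0,
                             n_outcome_samples=1000, binary_outcome=True,
                             prevalence=0.2)
        rng = np.random.default_rng(9)
        _, _, truth = simulate_cohort(p, rng)
        go, _, _ = simulate_cohort(p, rng, "out", n_samples=1000, truth=truth)
        y = simulate_outcome(truth, go, p, rng)
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert abs(y.mean() - 0.2) < 0.03

    def test_unknown_module_label(self):
        p, ge, ee, go, y, truth = self._two_cohorts(0.0, seed=13, n=100)
        truth.target_module = "no-such-module"
        with pytest.raises(ValueError, match="no-such-module"):
            simulate_outcome(truth, go, p)


class TestTwoSampleStats:
    def test_non_eqtl_snps_have_uniform_exposure_p(self):
        p = SimulationParams(seed=14, n_genes=100, module_sizes=(20,),
                             n_snps=300, eqtl_frac=0.2,
                             n_exposure_samples=500, n_outcome_samples=200)
        rng = np.random.default_rng(14)
        ge, ee, truth = simulate_cohort(p, rng, "exp")
        go, _, _ = simulate_cohort(p, rng, "out", n_samples=200, truth=truth)
        y = simulate_outcome(truth, go, p, rng)
        non_eqtl = [s for s in ge.snp_ids if s not in truth.eqtl_beta][:150]
        exp, _ = make_two_sample_stats(ee, ge, y, go, non_eqtl,
                                       truth.module_genes("cyan"))
        pv = np.array([r.p for r in exp])
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_eqtl_snps_recover_planted_sign(self):
        p = SimulationParams(seed=15, n_genes=100, module_sizes=(15,),
                             n_snps=300, eqtl_frac=1.0, eqtl_beta_sd=2.0,
                             n_exposure_samples=2000, n_outcome_samples=200)
        rng = np.random.default_rng(15)
        ge, ee, truth = simulate_cohort(p, rng, "exp")
        go, _, _ = simulate_cohort(p, rng, "out", n_samples=200, truth=truth)
        y = simulate_outcome(truth, go, p, rng)
        exp, _ = make_two_sample_stats(ee, ge, y, go, truth.instrument_snps(),
                                       truth.module_genes("cyan"))
        agree = total = 0
        for r in exp:
            if abs(r.beta) > 2 * r.se:
                total += 1
                agree += np.sign(r.beta) == np.sign(truth.eqtl_beta[r.snp.snp_id])
        assert total > 0 and agree / total > 0.9


def test_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(module_sizes=(1000, 2000), n_genes=100)
    with pytest.raises(ValueError):
        SimulationParams(ld_rho=1.2)
    with pytest.raises(ValueError):
        SimulationParams(maf_range=(0.0, 0.5))
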