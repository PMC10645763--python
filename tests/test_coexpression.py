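"""Network construction: filtering, bicor, adjacency, TOM, cutting, merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetomod import coexpression as cx
from fetomod.io_formats import ExpressionMatrix
from fetomod.synthetic import SimulationParams, simulate_cohort


def _expr(values, prefix="g"):
    values = np.asarray(values, float)
    return ExpressionMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])], values)


class TestFilterGenes:
    def test_gene_below_expressed_fraction_dropped(self):
        # expressed in 37/42 samples = 88% < 90% threshold
        rng = np.random.default_rng(0)
        row = rng.gamma(2, 2, 42)
        row[:5] = 0.0
        keep_row = rng.gamma(2, 2, 42) + 0.1
        m = _expr(np.vstack([row, keep_row]))
        out = cx.filter_genes(m, 0.9)
        assert out.gene_ids == ["g1"]

    def test_constant_gene_dropped(self):
        rng = np.random.default_rng(1)
        m = _expr(np.vstack([np.full(10, 3.3), rng.gamma(2, 2, 10) + 0.1]))
        assert cx.filter_genes(m, 0.5).gene_ids == ["g1"]

    def test_all_pass_identity(self, toy_expression):
        out = cx.filter_genes(toy_expression, 0.9)
        assert out.gene_ids == toy_expression.gene_ids
        np.testing.assert_array_equal(out.values, toy_expression.values)

    def test_empty_result_is_error(self):
        m = _expr(np.zeros((3, 5)) + np.eye(3, 5))
        with pytest.raises(ValueError):
            cx.filter_genes(m, 0.9)


class TestSampleOutliers:
    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((100, 30))
        v[:, 7] += 10.0
        assert cx.detect_sample_outliers(_expr(v)) == ["s7"]

    def test_null_false_flag_rate(self):
        rng = np.random.default_rng(3)
        flagged = 0
        for _ in range(40):
            v = rng.standard_normal((80, 25))
            flagged += bool(cx.detect_sample_outliers(_expr(v)))
        assert flagged / 40 <= 0.05

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cx.detect_sample_outliers(_expr(np.ones((5, 3))))


class TestBicor:
    def test_identity_and_antitone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert cx.bicor(x, x) == pytest.approx(1.0)
        assert cx.bicor(x, x[::-1]) == pytest.approx(-1.0)

    def test_outlier_case_matches_direct_formula(self):
        """Independent step-by-step evaluation of the biweight formula."""
        x = np.array([1.0, 2, 3, 4, 100])
        y = np.array([1.0, 2, 3, 4, 5])

        def transform(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            u = (v - med) / (9 * mad)
            w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
            return (v - med) * w

        xt, yt = transform(x), transform(y)
        expected = (xt @ yt) / (np.linalg.norm(xt) * np.linalg.norm(yt))
        got = cx.bicor(x, y)
        assert got == pytest.approx(expected, abs=1e-12)
        # outlier influences bicor less than Pearson
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(got - 1.0) < abs(pearson - 1.0) or got > pearson

    def test_mad_zero_falls_back_to_pearson(self):
        x = np.array([1.0, 1, 1, 1, 9])  # MAD = 0
        y = np.array([2.0, 1, 3, 1, 9])
        assert cx.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_matrix_agrees_with_pairwise(self, toy_expression):
        c = cx.bicor_matrix(toy_expression.values)
        for i in (0, 3):
            for j in (5, 9):
                assert c[i, j] == pytest.approx(
                    cx.bicor(toy_expression.values[i], toy_expression.values[j]),
                    abs=1e-12)
        np.testing.assert_allclose(c, c.T, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_range_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 8))
        r = cx.bicor(x, y)
        assert -1.0 <= r <= 1.0


class TestAdjacencyAndTOM:
    def test_signed_endpoints_and_closed_form(self):
        params = cx.NetworkParams(soft_power=14)
        cor = np.array([[1.0, 1.0, -1.0, 0.0],
                        [1.0, 1.0, 0.0, 0.0],
                        [-1.0, 0.0, 1.0, 0.0],
                        [0.0, 0.0, 0.0, 1.0]])
        a = ((1 + cor) / 2) ** 14
        assert a[0, 1] == 1.0
        assert a[0, 2] == 0.0
        assert a[0, 3] == pytest.approx(0.5 ** 14)

    def test_adjacency_symmetric(self, toy_expression):
        a = cx.adjacency(toy_expression, cx.NetworkParams())
        np.testing.assert_allclose(a, a.T, atol=1e-12)
        assert a.min() >= 0 and a.max() <= 1

    def test_tom_three_gene_toy(self):
        """Hand evaluation: off-diagonal TOM = (0.25 + 0.5)/(1 + 1 - 0.5)."""
        a = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        t = cx.tom(a)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(t.values[iu], 0.5, atol=1e-12)
        np.testing.assert_allclose(np.diag(t.values), 1.0)

    def test_isolated_gene_row_tracks_adjacency(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.6
        a[2, :2] = a[:2, 2] = 1e-9
        a[3, :3] = a[:3, 3] = 1e-9
        t = cx.tom(a)
        np.testing.assert_allclose(t.values[3, :3], a[3, :3], atol=1e-6)

    def test_tom_range_and_symmetry(self, toy_expression):
        a = cx.adjacency(toy_expression, cx.NetworkParams(soft_power=6))
        t = cx.tom(a, toy_expression.gene_ids)
        assert t.values.min() >= 0 and t.values.max() <= 1
        np.testing.assert_allclose(t.values, t.values.T, atol=1e-12)


class TestSoftThreshold:
    def _structured(self, seed=0, n_genes=120, n_samples=80):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(n_samples)
        lam = rng.uniform(0.5, 0.9, n_genes)
        v = lam[:, None] * f + rng.standard_normal((n_genes, n_samples))
        return _expr(v + 8)

    def test_noise_has_poor_fit_at_power_one(self):
        rng = np.random.default_rng(4)
        m = _expr(rng.standard_normal((150, 60)) + 8)
        _, table = cx.pick_soft_threshold(m, candidate_powers=[1],
                                          target_r2=0.8)
        assert table["signed_r2"].iloc[0] < 0.8

    def test_gene_order_invariance(self):
        m = self._structured()
        p1, _ = cx.pick_soft_threshold(m, target_r2=0.5)
        perm = np.random.default_rng(1).permutation(m.n_genes)
        m2 = ExpressionMatrix([m.gene_ids[i] for i in perm],
                              m.sample_ids, m.values[perm])
        p2, _ = cx.pick_soft_threshold(m2, target_r2=0.5)
        assert p1 == p2

    def test_smallest_power_reaching_target_returned(self):
        m = self._structured()
        power, table = cx.pick_soft_threshold(m, target_r2=0.5)
        reached = table[table["signed_r2"] >= 0.5]
        if len(reached):
            assert power == reached["power"].iloc[0]

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            cx.pick_soft_threshold(_expr(np.random.default_rng(0)
                                         .standard_normal((10, 5))))


class TestCutModules:
    def test_two_separated_blocks_exact(self):
        p = SimulationParams(seed=4, n_genes=80, module_sizes=(40, 40),
                             n_snps=100, eqtl_frac=0.0,
                             n_exposure_samples=300)
        _, expr, truth = simulate_cohort(p)
        _, _, part, _ = cx.run_network(expr)
        assert len(part.modules()) == 2
        assert len(part.module_genes("grey")) == 0
        sizes = sorted(len(part.module_genes(m)) for m in part.modules())
        assert sizes == [40, 40]

    def test_all_noise_mostly_grey(self):
        grey_fracs = []
        for seed in range(3):
            p = SimulationParams(seed=seed, n_genes=300, module_sizes=(30,),
                                 loading_range=(0.0, 0.0), eqtl_frac=0.0,
                                 n_exposure_samples=150, n_snps=50)
            _, expr, _ = simulate_cohort(p)
            _, _, part, _ = cx.run_network(expr)
            grey_fracs.append(len(part.module_genes("grey")) / len(part.labels))
        assert np.mean(grey_fracs) >= 0.8

    def test_gene_order_invariance_up_to_renaming(self):
        p = SimulationParams(seed=8, n_genes=200, module_sizes=(50, 40),
                             n_snps=100, n_exposure_samples=200)
        _, expr, _ = simulate_cohort(p)
        _, _, part1, _ = cx.run_network(expr)
        perm = np.random.default_rng(0).permutation(expr.n_genes)
        expr2 = ExpressionMatrix([expr.gene_ids[i] for i in perm],
                                 expr.sample_ids, expr.values[perm])
        _, _, part2, _ = cx.run_network(expr2)
        from sklearn.metrics import adjusted_rand_score
        l1 = [part1.labels[g] for g in expr.gene_ids]
        l2 = [part2.labels[g] for g in expr.gene_ids]
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)


class TestEigengene:
    def test_two_identical_genes(self):
        rng = np.random.default_rng(5)
        profile = rng.standard_normal(30)
        m = _expr(np.vstack([profile, profile]))
        part = cx.ModulePartition({"g0": "m1", "g1": "m1"})
        em = cx.eigengene(m, part)
        assert em.var_explained["m1"] == pytest.approx(1.0)
        r = np.corrcoef(em.eigengenes["m1"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_orientation_positive_with_mean_profile(self, small_cohort):
        _, _, expr, truth = small_cohort
        part = cx.ModulePartition(dict(truth.module_of_gene))
        em = cx.eigengene(expr, part)
        for module, eg in em.eigengenes.items():
            sub = expr.subset_genes(part.module_genes(module))
            assert np.corrcoef(eg, sub.values.mean(axis=0))[0, 1] >= 0

    def test_matches_svd_oracle(self, small_cohort):
        _, _, expr, truth = small_cohort
        part = cx.ModulePartition(dict(truth.module_of_gene))
        em = cx.eigengene(expr, part)
        sub = expr.subset_genes(part.module_genes("cyan")).values
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        r = abs(np.corrcoef(em.eigengenes["cyan"], vt[0])[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_single_gene_module_error(self, toy_expression):
        part = cx.ModulePartition({g: ("m1" if g == "g0" else "grey")
                                   for g in toy_expression.gene_ids})
        with pytest.raises(ValueError):
            cx.eigengene(toy_expression, part)


class TestMergeModules:
    def _split_factor(self):
        """One latent factor artificially split into two module labels."""
        rng = np.random.default_rng(6)
        f = rng.standard_normal(60)
        lam = rng.uniform(0.6, 0.9, 40)
        v = lam[:, None] * f + 0.6 * rng.standard_normal((40, 60))
        m = _expr(v)
        labels = {g: ("a" if i < 20 else "b") for i, g in enumerate(m.gene_ids)}
        return m, cx.ModulePartition(labels)

    def test_split_factor_merges(self):
        m, part = self._split_factor()
        merged = cx.merge_modules(m, part, threshold=0.85)
        assert len(merged.modules()) == 1

    def test_threshold_one_no_merges(self):
        m, part = self._split_factor()
        merged = cx.merge_modules(m, part, threshold=1.0)
        assert merged.labels == part.labels

    def test_idempotent(self, small_cohort):
        _, _, expr, truth = small_cohort
        part = cx.ModulePartition(dict(truth.module_of_gene))
        once = cx.merge_modules(expr, part, 0.85)
        twice = cx.merge_modules(expr, once, 0.85)
        assert once.labels == twice.labels
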