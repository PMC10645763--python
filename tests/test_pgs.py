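"""Expression PGS: SNP-gene mapping, clumping, scoring, negative controls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetomod import pgs as P
from fetomod.io_formats import EQTLRecord, GenotypeMatrix, VariantInfo
from fetomod.synthetic import simulate_genotypes


def _variant(snp, pos, ea="A", oa="G", chrom="1"):
    return VariantInfo(snp, chrom, pos, ea, oa)


def _eqtl(snp, pos, gene, beta, p, ea="A", oa="G"):
    return EQTLRecord(_variant(snp, pos, ea, oa), gene, beta, 0.05, p)


class TestMapSnpsToGenes:
    ANN = {"gA": P.GeneAnnotation("gA", "1", 1000, 2000),
           "gB": P.GeneAnnotation("gB", "1", 1950, 3000)}

    def test_boundaries_inclusive(self):
        variants = [_variant("rs1", 1000), _variant("rs2", 2000),
                    _variant("rs3", 2001)]
        pairs = P.map_snps_to_genes(variants, self.ANN, genes=["gA"])
        assert pairs == [("rs1", "gA"), ("rs2", "gA")]

    def test_window_extends_gene_body(self):
        variants = [_variant("rs1", 2001)]
        assert P.map_snps_to_genes(variants, self.ANN, genes=["gA"]) == []
        pairs = P.map_snps_to_genes(variants, self.ANN, genes=["gA"],
                                    window_kb=1.0)
        assert pairs == [("rs1", "gA")]

    def test_overlapping_genes_emit_two_pairs(self):
        variants = [_variant("rs1", 1975)]
        pairs = P.map_snps_to_genes(variants, self.ANN)
        assert sorted(pairs) == [("rs1", "gA"), ("rs1", "gB")]

    def test_missing_annotation_skipped(self):
        pairs = P.map_snps_to_genes([_variant("rs1", 1500)], self.ANN,
                                    genes=["gA", "gZ"])
        assert pairs == [("rs1", "gA")]


class TestLDClump:
    def _reference(self, r):
        """Two SNPs with dosage correlation ~ sqrt(r)."""
        rng = np.random.default_rng(0)
        n = 4000
        base = rng.binomial(2, 0.3, n).astype(float)
        noise = rng.binomial(2, 0.3, n).astype(float)
        mix = np.where(rng.uniform(size=n) < np.sqrt(r), base, noise)
        variants = [_variant("rs1", 1000), _variant("rs2", 2000)]
        return GenotypeMatrix([f"i{k}" for k in range(n)], variants,
                              np.column_stack([base, mix]))

    def test_correlated_pair_pruned(self):
        ref = self._reference(0.8)
        eqtls = [_eqtl("rs1", 1000, "gA", 0.5, 1e-8),
                 _eqtl("rs2", 2000, "gA", 0.4, 1e-4)]
        kept = P.ld_clump(eqtls, ref, r2_threshold=0.2)
        assert [k.snp.snp_id for k in kept] == ["rs1"]

    def test_boundary_low_r2_both_retained(self):
        ref = self._reference(0.0)
        eqtls = [_eqtl("rs1", 1000, "gA", 0.5, 1e-8),
                 _eqtl("rs2", 2000, "gA", 0.4, 1e-4)]
        kept = P.ld_clump(eqtls, ref, r2_threshold=0.2)
        assert len(kept) == 2

    def test_order_invariance_with_distinct_p(self):
        geno = simulate_genotypes(500, 30, 10, 0.8, (0.2, 0.4), seed=1)
        rng = np.random.default_rng(2)
        eqtls = [EQTLRecord(v, "gA", 0.3, 0.05, p)
                 for v, p in zip(geno.variants,
                                 rng.uniform(1e-10, 1e-2, 30))]
        a = P.ld_clump(eqtls, geno)
        b = P.ld_clump(list(reversed(eqtls)), geno)
        assert [x.snp.snp_id for x in a] == [x.snp.snp_id for x in b]

    def test_clump_invariants(self):
        """Kept set is a subset; every removed SNP is tagged by a kept SNP
        with smaller p at r^2 above threshold."""
        geno = simulate_genotypes(1000, 40, 10, 0.9, (0.2, 0.4), seed=3)
        rng = np.random.default_rng(4)
        eqtls = [EQTLRecord(v, "gA", 0.3, 0.05, p)
                 for v, p in zip(geno.variants, rng.uniform(1e-10, 1e-2, 40))]
        kept = P.ld_clump(eqtls, geno, r2_threshold=0.2)
        kept_ids = {k.snp.snp_id for k in kept}
        assert kept_ids <= {e.snp.snp_id for e in eqtls}
        p_of = {e.snp.snp_id: e.p for e in eqtls}
        col = {s: i for i, s in enumerate(geno.snp_ids)}
        for e in eqtls:
            if e.snp.snp_id in kept_ids:
                continue
            tags = []
            for k in kept:
                r = np.corrcoef(geno.dosages[:, col[e.snp.snp_id]],
                                geno.dosages[:, col[k.snp.snp_id]])[0, 1]
                if r ** 2 >= 0.2 and p_of[k.snp.snp_id] <= e.p:
                    tags.append(k.snp.snp_id)
            assert tags, f"{e.snp.snp_id} removed without a tagging SNP"


class TestBuildPGS:
    def _geno(self):
        variants = [_variant("rs1", 1000, "A", "G"),
                    _variant("rs2", 2000, "C", "A"),
                    _variant("rs3", 3000, "G", "C")]
        dos = np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        return GenotypeMatrix(["i1", "i2"], variants, dos)

    def test_single_snp_weight_one_is_dosage(self):
        g = self._geno()
        w = P.PGSWeights([(g.variants[0], 1.0, "gA")])
        np.testing.assert_allclose(P.build_pgs(g, w).scores, [0.0, 2.0])

    def test_allele_flip_identity(self):
        g = self._geno()
        w1 = P.PGSWeights([(_variant("rs1", 1000, "A", "G"), 0.7, "gA")])
        w2 = P.PGSWeights([(_variant("rs1", 1000, "G", "A"), -0.7, "gA")])
        s1 = P.build_pgs(g, w1).scores
        s2 = P.build_pgs(g, w2).scores
        np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-12)

    def test_hand_computed_weighted_sum(self):
        g = self._geno()
        w = P.PGSWeights([(g.variants[0], 0.5, "gA"),
                          (g.variants[1], -0.25, "gB"),
                          (g.variants[2], 1.0, "gC")])
        expected = np.array([0.5 * 0 - 0.25 * 1 + 1 * 2,
                             0.5 * 2 - 0.25 * 0 + 1 * 1])
        np.testing.assert_allclose(P.build_pgs(g, w).scores, expected,
                                   atol=1e-12)

    def test_mismatched_alleles_dropped(self):
        g = self._geno()
        w = P.PGSWeights([(_variant("rs1", 1000, "A", "C"), 5.0, "gA"),
                          (g.variants[2], 1.0, "gC")])
        vec = P.build_pgs(g, w)
        assert vec.n_snps_used == 1
        np.testing.assert_allclose(vec.scores, [2.0, 1.0])

    def test_missing_policies(self):
        variants = [_variant("rs1", 1000)]
        dos = np.array([[np.nan], [2.0], [0.0]])
        g = GenotypeMatrix(["i1", "i2", "i3"], variants, dos)
        w = P.PGSWeights([(variants[0], 1.0, "gA")])
        np.testing.assert_allclose(P.build_pgs(g, w, "mean").scores,
                                   [1.0, 2.0, 0.0])
        np.testing.assert_allclose(P.build_pgs(g, w, "zero").scores,
                                   [0.0, 2.0, 0.0])
        assert P.build_pgs(g, w, "drop").n_snps_used == 0

    def test_linearity_in_weights(self):
        g = self._geno()
        wa = P.PGSWeights([(g.variants[0], 0.3, "gA"),
                           (g.variants[1], 0.2, "gB")])
        wb = P.PGSWeights([(g.variants[0], -0.1, "gA"),
                           (g.variants[1], 0.5, "gB")])
        wsum = P.PGSWeights([(g.variants[0], 0.2, "gA"),
                             (g.variants[1], 0.7, "gB")])
        np.testing.assert_allclose(
            P.build_pgs(g, wsum).scores,
            P.build_pgs(g, wa).scores + P.build_pgs(g, wb).scores,
            atol=1e-12)

    def test_duplicate_snp_weights_rejected(self):
        g = self._geno()
        with pytest.raises(ValueError):
            P.PGSWeights([(g.variants[0], 1.0, "gA"),
                          (g.variants[0], 2.0, "gB")])


class TestWeightsFromEqtls:
    def test_snp_on_two_genes_contributes_once_smaller_p(self):
        eqtls = [_eqtl("rs1", 1000, "gA", 0.5, 1e-4),
                 _eqtl("rs1", 1000, "gB", 0.9, 1e-8)]
        w = P.weights_from_eqtls(eqtls, ["gA", "gB"])
        assert len(w.entries) == 1
        assert w.entries[0][1] == 0.9  # smaller-p record kept


class TestNegativeControls:
    def test_random_genes_reproducible(self):
        universe = [f"g{i}" for i in range(100)]
        a = P.negative_control_genes("random_genes", 10, 3, universe=universe)
        b = P.negative_control_genes("random_genes", 10, 3, universe=universe)
        assert a == b and len(set(a)) == 10

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            P.negative_control_genes("random_genes", 10, 0, universe=["g1"])

    def test_all_zero_alt_weights_give_constant_pgs(self):
        variants = [_variant("rs1", 1000), _variant("rs2", 2000)]
        g = GenotypeMatrix(["i1", "i2"], variants,
                           np.array([[0.0, 1.0], [2.0, 1.0]]))
        eqtls = [EQTLRecord(v, f"g{k}", 0.0, 0.05, 1e-4)
                 for k, v in enumerate(variants)]
        w = P.negative_control_pgs("alternative_tissue_weights", 2, 0, eqtls,
                                   module_genes=["g0", "g1"])
        scores = P.build_pgs(g, w).scores
        np.testing.assert_allclose(scores, scores[0])


class TestValidatePGS:
    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(100)
        y = 0.5 * scores + rng.standard_normal(100)
        v1 = P.PGSVector([f"i{k}" for k in range(100)], scores)
        v2 = P.PGSVector([f"i{k}" for k in range(100)], scores + 42.0)
        assert P.validate_pgs(v1, y).p == pytest.approx(P.validate_pgs(v2, y).p)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(50)
        y = rng.standard_normal(50)
        v = P.PGSVector([f"i{k}" for k in range(50)], scores)
        cov = np.column_stack([scores, scores * 2.0])
        with pytest.raises(ValueError, match="ill-conditioned"):
            P.validate_pgs(v, y, covariates=cov)

    def test_permuted_pgs_null(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(100):
            scores = rng.standard_normal(120)
            y = rng.standard_normal(120)
            v = P.PGSVector([f"i{k}" for k in range(120)], scores)
            ps.append(P.validate_pgs(v, y).p)
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.12


@given(st.integers(0, 10_000))
def test_clumped_set_subset_of_input(seed):
    geno = simulate_genotypes(200, 20, 5, 0.7, (0.2, 0.4), seed=seed % 50)
    rng = np.random.default_rng(seed)
    eqtls = [EQTLRecord(v, "gA", 0.3, 0.05, p)
             for v, p in zip(geno.variants, rng.uniform(1e-9, 1e-2, 20))]
    kept = P.ld_clump(eqtls, geno)
    assert {k.snp.snp_id for k in kept} <= {e.snp.snp_id for e in eqtls}
    assert len(kept) >= 1
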