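"""eQTL-weighted module-expression polygenic scores and negative controls.

The score for an individual is the sum, over LD-clumped SNPs that are
eQTLs for a module's genes, of effect-allele dosage times the eQTL effect
size on gene expression.  Negative controls keep the construction identical
but swap in (a) a size-matched different module, (b) a random gene list of
the same size, or (c) the same module weighted by another tissue's eQTLs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .io_formats import EQTLRecord, GenotypeMatrix, VariantInfo

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass
class PGSWeights:
    entries: list[tuple[VariantInfo, float, str]]  # (variant, weight, source gene)
    provenance: str = "module"
    clump_r2: float | None = None
    clump_window_kb: float | None = None

    def __post_init__(self) -> None:
        ids = [v.snp_id for v, _, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("PGSWeights must contain one weight per SNP")

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v, _, _ in self.entries]


@dataclass
class PGSVector:
    sample_ids: list[str]
    scores: np.ndarray
    provenance: str = "module"
    n_snps_used: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.scores):
            raise ValueError("score length must equal cohort size")


@dataclass
class RegressionReport:
    beta: float
    se: float
    p: float
    n: int
    term: str = "pgs"
    covariate_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# SNP -> gene mapping and clumping
# ---------------------------------------------------------------------------

def map_snps_to_genes(variants: Sequence[VariantInfo],
                      annotations: Mapping[str, GeneAnnotation] | Sequence[GeneAnnotation],
                      genes: Sequence[str] | None = None,
                      window_kb: float = 0.0) -> list[tuple[str, str]]:
    """(snp_id, gene_id) pairs for SNPs inside gene bodies +/- window.

    Boundaries are inclusive; the default window of 0 kb means "located on
    the gene".  A SNP overlapping several genes yields several pairs.
    Requested genes lacking an annotation are skipped with a log message.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.gene_id: a for a in annotations}
    wanted = list(genes) if genes is not None else list(annotations)
    pairs: list[tuple[str, str]] = []
    w = window_kb * 1000.0
    for g in wanted:
        ann = annotations.get(g)
        if ann is None:
            logger.info("map_snps_to_genes: no annotation for %s, skipped", g)
            continue
        lo, hi = ann.start - w, ann.end + w
        for v in variants:
            if v.chrom == ann.chrom and lo <= v.pos <= hi:
                pairs.append((v.snp_id, g))
    return pairs


def ld_clump(eqtls: Sequence[EQTLRecord],
             reference: GenotypeMatrix,
             r2_threshold: float = 0.2,
             window_kb: float = 250.0) -> list[EQTLRecord]:
    """Greedy p-value-ordered LD clumping.

    Accept the smallest-p SNP, discard every remaining SNP within the
    window whose dosage r^2 with it reaches ``r2_threshold``, repeat.  SNPs
    absent from the reference panel pass through with a warning (they prune
    nothing and are never pruned).
    """
    ref_idx = {s: i for i, s in enumerate(reference.snp_ids)}
    ordered = sorted(eqtls, key=lambda r: (r.p, r.snp.snp_id))
    kept: list[EQTLRecord] = []
    removed: set[str] = set()
    window = window_kb * 1000.0
    for i, rec in enumerate(ordered):
        sid = rec.snp.snp_id
        if sid in removed:
            continue
        kept.append(rec)
        if sid not in ref_idx:
            logger.warning("ld_clump: %s absent from reference panel", sid)
            continue
        d_index = reference.dosages[:, ref_idx[sid]]
        for other in ordered[i + 1:]:
            oid = other.snp.snp_id
            if oid in removed or oid not in ref_idx:
                continue
            if other.snp.chrom != rec.snp.chrom or abs(other.snp.pos - rec.snp.pos) > window:
                continue
            r2 = _dosage_r2(d_index, reference.dosages[:, ref_idx[oid]])
            if r2 >= r2_threshold:
                removed.add(oid)
    return kept


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# weights and scoring
# ---------------------------------------------------------------------------

def weights_from_eqtls(eqtls: Sequence[EQTLRecord],
                       genes: Sequence[str],
                       reference: GenotypeMatrix | None = None,
                       r2_threshold: float = 0.2,
                       window_kb: float = 250.0,
                       provenance: str = "module") -> PGSWeights:
    """Restrict an eQTL table to a gene list, deduplicate SNPs, clump.

    A SNP that is an eQTL for two listed genes contributes once, keeping
    the smaller-p record (logged).
    """
    gene_set = set(genes)
    hits = [r for r in eqtls if r.gene_id in gene_set]
    by_snp: dict[str, EQTLRecord] = {}
    for r in sorted(hits, key=lambda r: (r.p, r.gene_id)):
        if r.snp.snp_id in by_snp:
            logger.info("weights_from_eqtls: %s maps to several genes; "
                        "keeping smallest-p record", r.snp.snp_id)
            continue
        by_snp[r.snp.snp_id] = r
    records = list(by_snp.values())
    if reference is not None:
        records = ld_clump(records, reference, r2_threshold, window_kb)
    return PGSWeights([(r.snp, r.beta, r.gene_id) for r in records],
                      provenance=provenance, clump_r2=r2_threshold,
                      clump_window_kb=window_kb)


def build_pgs(genotypes: GenotypeMatrix, weights: PGSWeights,
              missing_policy: str = "mean") -> PGSVector:
    """Weighted effect-allele dosage sum per sample.

    Allele orientation is checked per SNP: matching alleles use the dosage
    as-is; swapped effect/other alleles flip the dosage to ``2 - d``; any
    other mismatch drops the SNP with a log message.  Missing dosages are
    imputed to the in-cohort mean (2 x EAF) by default; ``zero`` scores
    missing calls as 0 copies and ``drop`` excludes SNPs with any missing
    call.
    """
    if not weights.entries:
        raise ValueError("weights are empty")
    if missing_policy not in ("mean", "drop", "zero"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    geno_by_id = {v.snp_id: i for i, v in enumerate(genotypes.variants)}
    score = np.zeros(len(genotypes.sample_ids))
    used = 0
    for variant, weight, _gene in weights.entries:
        j = geno_by_id.get(variant.snp_id)
        if j is None:
            logger.info("build_pgs: %s not genotyped, skipped", variant.snp_id)
            continue
        gv = genotypes.variants[j]
        if (variant.effect_allele, variant.other_allele) == (gv.effect_allele, gv.other_allele):
            d = genotypes.dosages[:, j].copy()
        elif (variant.effect_allele, variant.other_allele) == (gv.other_allele, gv.effect_allele):
            d = 2.0 - genotypes.dosages[:, j]
        else:
            logger.warning("build_pgs: allele mismatch for %s (%s/%s vs %s/%s), dropped",
                           variant.snp_id, variant.effect_allele, variant.other_allele,
                           gv.effect_allele, gv.other_allele)
            continue
        miss = np.isnan(d)
        if miss.any():
            if missing_policy == "drop":
                logger.info("build_pgs: %s has missing calls, dropped", variant.snp_id)
                continue
            if missing_policy == "zero":
                d[miss] = 0.0
            else:
                d[miss] = np.nanmean(d)
        score += weight * d
        used += 1
    return PGSVector(list(genotypes.sample_ids), score,
                     provenance=weights.provenance, n_snps_used=used)


def negative_control_genes(mode: str, size: int, seed: int,
                           universe: Sequence[str] | None = None,
                           module_genes: Sequence[str] | None = None) -> list[str]:
    """Gene list for a negative-control score.

    ``random_genes`` draws ``size`` genes uniformly without replacement from
    the expressed-gene universe; ``size_matched_module`` and
    ``alternative_tissue_weights`` return the supplied gene list unchanged
    (the control lives in which genes / which weights are used downstream).
    """
    if mode == "random_genes":
        if universe is None or len(universe) < size:
            raise ValueError("universe smaller than requested control size")
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(universe), size=size, replace=False)
        return [universe[i] for i in picked]
    if mode in ("size_matched_module", "alternative_tissue_weights"):
        if module_genes is None:
            raise ValueError(f"mode {mode!r} needs an explicit gene list")
        return list(module_genes)
    raise ValueError(f"unknown control mode {mode!r}")


def negative_control_pgs(mode: str, size: int, seed: int,
                         eqtls: Sequence[EQTLRecord],
                         universe: Sequence[str] | None = None,
                         module_genes: Sequence[str] | None = None,
                         reference: GenotypeMatrix | None = None,
                         r2_threshold: float = 0.2,
                         window_kb: float = 250.0) -> PGSWeights:
    """Weights for one of the three negative-control constructions.

    For ``alternative_tissue_weights`` pass the *alternative* eQTL table as
    ``eqtls``; the gene set stays the target module's.
    """
    genes = negative_control_genes(mode, size, seed, universe, module_genes)
    return weights_from_eqtls(eqtls, genes, reference, r2_threshold,
                              window_kb, provenance=mode)


def validate_pgs(pgs: PGSVector, module_scores: np.ndarray,
                 covariates: np.ndarray | None = None,
                 covariate_names: Sequence[str] | None = None) -> RegressionReport:
    """OLS of a per-sample module score on the PGS plus covariates."""
    y = np.asarray(module_scores, float)
    if len(y) != len(pgs.scores):
        raise ValueError("module scores not aligned with PGS samples")
    cols = [np.ones(len(y)), np.asarray(pgs.scores, float)]
    names = ["const", "pgs"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] == len(y):
            cov = cov.T
        for k, row in enumerate(cov):
            cols.append(row)
            names.append(covariate_names[k] if covariate_names else f"cov{k}")
    X = np.column_stack(cols)
    if np.linalg.cond(X) > 1e10:
        raise ValueError("design matrix is ill-conditioned (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    return RegressionReport(float(fit.params[1]), float(fit.bse[1]),
                            float(fit.pvalues[1]), int(fit.nobs),
                            covariate_names=names[2:])
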