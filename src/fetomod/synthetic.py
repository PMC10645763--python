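"""Ground-truth generator: genotypes -> co-expressed modules -> adult outcome.

The generative model mirrors the causal diagram the analysis chain is meant
to recover:

* LD-blocked biallelic genotypes (equicorrelated-Gaussian haplotypes
  thresholded at the 1-MAF quantile, dosage = sum of two haplotypes);
* gene expression ``X[g,s] = baseline + beta_g * d[s, j(g)]
  + lambda_g * F[m(g), s] + eps`` with per-module latent factors F,
  uniform loadings for module genes, and cis-eQTL effects for a random
  fraction of each module's genes;
* an adult outcome, measured in an independent cohort, causally downstream
  of the target module's genetically determined activity (effect ``gamma``),
  optionally with pleiotropic instrument effects that bypass the module.

Two independent cohorts (exposure / outcome) enforce the two-sample MR
structure; there is no sample overlap and no reverse causation.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimulationParams.seed`` (PCG64), so runs are fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import (EQTLRecord, ExpressionMatrix, GenotypeMatrix,
                         GWASSummaryRecord, VariantInfo)

logger = logging.getLogger(__name__)

MODULE_COLORS = ("cyan", "blue", "brown", "salmon", "magenta",
                 "turquoise", "green", "yellow", "purple", "pink")
GREY = "grey"


@dataclass
class SimulationParams:
    n_exposure_samples: int = 1000
    n_outcome_samples: int = 1000
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (100, 100, 80, 60, 50)
    n_snps: int = 1000
    ld_block_size: int = 10
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_frac: float = 0.3
    background_eqtl_frac: float = 0.0  # cis-eQTL fraction for non-module genes
    eqtl_beta_sd: float = 0.3
    eqtl_positive_frac: float | None = None  # None -> sign as drawn
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 1.0
    baseline_expression: float = 8.0
    gamma: float = -0.3
    target_module: str = MODULE_COLORS[0]
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.1
    pleiotropy_directional: bool = False  # True: delta = |N(0, sd^2)|
    binary_outcome: bool = False
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exposure_samples, self.n_outcome_samples,
               self.n_genes, self.n_snps, self.ld_block_size) < 1:
            raise ValueError("all sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) must be <= n_genes")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for name in ("eqtl_frac", "background_eqtl_frac", "pleiotropy_frac",
                     "prevalence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.module_sizes) > len(MODULE_COLORS):
            raise ValueError("too many modules for the label palette")

    @property
    def module_labels(self) -> tuple[str, ...]:
        return MODULE_COLORS[: len(self.module_sizes)]


@dataclass
class SimulationTruth:
    """Planted structure: the answer key every recovery test grades against."""

    module_of_gene: dict[str, str]            # gene id -> module label (or grey)
    loadings: dict[str, float]                # gene id -> factor loading
    eqtl_snp_of_gene: dict[str, str]          # gene id -> cis-eQTL snp id
    eqtl_beta: dict[str, float]               # snp id -> true beta on its gene
    factor_scores: np.ndarray                 # modules x samples (exposure cohort)
    gamma: float
    target_module: str
    pleiotropy_delta: dict[str, float] = field(default_factory=dict)

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]

    def instrument_snps(self, label: str | None = None) -> list[str]:
        label = label or self.target_module
        return [self.eqtl_snp_of_gene[g] for g in self.module_genes(label)
                if g in self.eqtl_snp_of_gene]


def simulate_genotypes(n: int, n_snps: int, block_size: int, rho: float,
                       maf_range: tuple[float, float],
                       seed: int | np.random.Generator) -> GenotypeMatrix:
    """LD-blocked dosages: equicorrelated-Gaussian haplotypes per block.

    Within a block each haplotype's latent value is
    ``sqrt(rho) * shared + sqrt(1-rho) * private``, thresholded at the
    (1 - MAF) normal quantile; the dosage is the sum of two independent
    haplotypes.  Blocks sit on chromosome 1 at 1 kb spacing with 1 Mb gaps
    between blocks, so within-block pairs fall inside any sensible clumping
    window and between-block pairs do not.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    thresholds = stats.norm.ppf(1.0 - mafs)
    n_blocks = int(np.ceil(n_snps / block_size))
    dosages = np.zeros((n, n_snps))
    for _ in range(2):  # two haplotypes
        hap = np.empty((n, n_snps))
        for b in range(n_blocks):
            s = slice(b * block_size, min((b + 1) * block_size, n_snps))
            width = s.stop - s.start
            shared = rng.standard_normal((n, 1))
            private = rng.standard_normal((n, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * private
            hap[:, s] = latent > thresholds[s]
        dosages += hap
    variants = [
        VariantInfo(f"snp{j:04d}", "1",
                    (j // block_size) * 1_000_000 + (j % block_size) * 1_000 + 1,
                    "A", "G")
        for j in range(n_snps)
    ]
    samples = [f"s{i:04d}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosages)


def simulate_cohort(params: SimulationParams,
                    rng: np.random.Generator | None = None,
                    sample_prefix: str = "exp",
                    n_samples: int | None = None,
                    truth: SimulationTruth | None = None,
                    ) -> tuple[GenotypeMatrix, ExpressionMatrix, SimulationTruth]:
    """Draw one cohort: genotypes, expression, and (on first call) the truth.

    Passing an existing ``truth`` reuses the planted structure (module
    membership, loadings, eQTL assignments) with fresh samples — that is how
    the independent outcome cohort and replicate datasets are generated.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = n_samples if n_samples is not None else params.n_exposure_samples

    geno = simulate_genotypes(n, params.n_snps, params.ld_block_size,
                              params.ld_rho, params.maf_range, rng)
    geno.sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n)]

    gene_ids = [f"g{i:04d}" for i in range(params.n_genes)]
    if truth is None:
        truth = _plant_structure(params, gene_ids, rng)

    labels = params.module_labels
    factors = rng.standard_normal((len(labels), n))
    expr = params.baseline_expression + rng.normal(
        0.0, params.noise_sd, size=(params.n_genes, n))
    snp_col = {v.snp_id: k for k, v in enumerate(geno.variants)}
    mod_row = {m: k for k, m in enumerate(labels)}
    for i, g in enumerate(gene_ids):
        m = truth.module_of_gene[g]
        if m != GREY:
            expr[i] += truth.loadings[g] * factors[mod_row[m]]
        snp = truth.eqtl_snp_of_gene.get(g)
        if snp is not None:
            expr[i] += truth.eqtl_beta[snp] * geno.dosages[:, snp_col[snp]]
    truth = SimulationTruth(truth.module_of_gene, truth.loadings,
                            truth.eqtl_snp_of_gene, truth.eqtl_beta,
                            factors, params.gamma, params.target_module,
                            truth.pleiotropy_delta)
    return geno, ExpressionMatrix(gene_ids, geno.sample_ids, expr), truth


def _plant_structure(params: SimulationParams, gene_ids: list[str],
                     rng: np.random.Generator) -> SimulationTruth:
    order = rng.permutation(params.n_genes)
    module_of_gene = {g: GREY for g in gene_ids}
    loadings = {g: 0.0 for g in gene_ids}
    start = 0
    members: dict[str, list[str]] = {}
    for label, size in zip(params.module_labels, params.module_sizes):
        idx = order[start:start + size]
        members[label] = [gene_ids[i] for i in idx]
        for g in members[label]:
            module_of_gene[g] = label
            loadings[g] = rng.uniform(*params.loading_range)
        start += size

    # one cis-eQTL for a random fraction of each module's genes; eQTL SNPs
    # are drawn from distinct LD blocks so planted instruments are
    # approximately independent (as clumped real instruments would be)
    n_blocks = int(np.ceil(params.n_snps / params.ld_block_size))
    block_order = list(rng.permutation(n_blocks))
    eqtl_snp_of_gene: dict[str, str] = {}
    eqtl_beta: dict[str, float] = {}
    pleio: dict[str, float] = {}
    recipients: list[tuple[str, bool]] = []
    for label in params.module_labels:
        k = int(round(params.eqtl_frac * len(members[label])))
        chosen = rng.choice(len(members[label]), size=k, replace=False)
        recipients.extend((members[label][c], True) for c in chosen)
    grey_genes = [g for g in gene_ids if module_of_gene[g] == GREY]
    if params.background_eqtl_frac > 0 and grey_genes:
        k = int(round(params.background_eqtl_frac * len(grey_genes)))
        chosen = rng.choice(len(grey_genes), size=k, replace=False)
        recipients.extend((grey_genes[c], False) for c in chosen)
    for gene, in_module in recipients:
        if block_order:  # one eQTL per LD block while blocks remain
            b = block_order.pop()
            j = b * params.ld_block_size + int(
                rng.integers(min(params.ld_block_size,
                                 params.n_snps - b * params.ld_block_size)))
        else:
            used = set(eqtl_beta)
            free = [s for s in range(params.n_snps) if f"snp{s:04d}" not in used]
            j = int(rng.choice(free))
        snp = f"snp{j:04d}"
        beta = float(rng.normal(0.0, params.eqtl_beta_sd))
        if params.eqtl_positive_frac is not None and rng.uniform() < params.eqtl_positive_frac:
            beta = abs(beta)
        eqtl_snp_of_gene[gene] = snp
        eqtl_beta[snp] = beta
        if in_module and rng.uniform() < params.pleiotropy_frac:
            delta = float(rng.normal(0.0, params.pleiotropy_sd))
            pleio[snp] = abs(delta) if params.pleiotropy_directional else delta
    return SimulationTruth(module_of_gene, loadings, eqtl_snp_of_gene,
                           eqtl_beta, np.empty((0, 0)), params.gamma,
                           params.target_module, pleio)


def genetic_module_activity(truth: SimulationTruth, geno: GenotypeMatrix,
                            params: SimulationParams,
                            module: str | None = None) -> np.ndarray:
    """True genetically determined activity of a module, on the scale of the
    standardized first principal component of the module's expression.

    Module genes are standardized before the PC1 is taken, so gene g enters
    with factor loading ``u_g = lambda_g / sigma_g`` where
    ``sigma_g^2 = lambda_g^2 + beta_g^2 var(d_g) + noise_sd^2`` is its total
    variance.  The standardized PC1 then responds to eQTL SNP j (acting on
    gene g) with per-allele slope ``u_g beta_j / (sigma_g ||u|| sd_t)``,
    ``sd_t^2 = ||u||^2 + sum_g (u_g/||u||)^2 (beta_g^2 var(d_g) +
    noise_sd^2) / sigma_g^2``.  Accumulating those slopes over the true
    eQTL map puts the genetic activity on the same scale as the measured
    exposure, so per-SNP Wald ratios concentrate at gamma.
    """
    module = module or truth.target_module
    genes = list(truth.module_genes(module))
    noise_var = params.noise_sd ** 2
    snp_col = {v.snp_id: k for k, v in enumerate(geno.variants)}

    lam = np.array([truth.loadings[g] for g in genes])
    beta = np.zeros(len(genes))
    var_d = np.zeros(len(genes))
    dos = np.zeros((len(geno.sample_ids), len(genes)))
    for i, g in enumerate(genes):
        snp = truth.eqtl_snp_of_gene.get(g)
        if snp is None:
            continue
        d = geno.dosages[:, snp_col[snp]]
        beta[i] = truth.eqtl_beta[snp]
        var_d[i] = float(np.var(d))
        dos[:, i] = d
    sigma2 = lam ** 2 + beta ** 2 * var_d + noise_var
    u = lam / np.sqrt(sigma2)
    u_norm = float(np.linalg.norm(u))
    w = u / u_norm
    var_t = u_norm ** 2 + float((w ** 2 * (beta ** 2 * var_d + noise_var) / sigma2).sum())
    raw = dos @ (u * beta / np.sqrt(sigma2))
    return raw / (u_norm * np.sqrt(var_t))


def simulate_outcome(truth: SimulationTruth, geno: GenotypeMatrix,
                     params: SimulationParams,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Outcome liability downstream of the target module's genetic activity.

    ``L = gamma * M + sum_pleiotropic delta_j * d_j + e``; a binary outcome
    thresholds L at the prevalence quantile.
    """
    if truth.target_module not in truth.module_of_gene.values():
        raise ValueError(f"unknown module label {truth.target_module!r}")
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    m = genetic_module_activity(truth, geno, params)
    liability = params.gamma * m + rng.standard_normal(len(geno.sample_ids))
    snp_col = {v.snp_id: k for k, v in enumerate(geno.variants)}
    for snp, delta in truth.pleiotropy_delta.items():
        liability += delta * geno.dosages[:, snp_col[snp]]
    if params.binary_outcome:
        cut = np.quantile(liability, 1.0 - params.prevalence)
        return (liability > cut).astype(float)
    return liability


def measured_module_activity(expr: ExpressionMatrix,
                             module_genes: Sequence[str]) -> np.ndarray:
    """Standardized PC1 of the module's expression, oriented so it correlates
    positively with the module's mean expression profile (the observable
    proxy an eQTL study would use for module activity)."""
    genes = [g for g in module_genes if g in expr.gene_ids]
    sub = expr.subset_genes(genes).values
    z = (sub - sub.mean(axis=1, keepdims=True))
    sd = z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z /= sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    if np.corrcoef(pc1, sub.mean(axis=0))[0, 1] < 0:
        pc1 = -pc1
    return (pc1 - pc1.mean()) / pc1.std(ddof=0)


def _per_snp_ols(y: np.ndarray, dosages: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form simple-OLS slope/se/p of y on each dosage column."""
    n = len(y)
    yc = y - y.mean()
    dc = dosages - dosages.mean(axis=0)
    var_d = (dc ** 2).sum(axis=0)
    beta = (dc * yc[:, None]).sum(axis=0) / var_d
    resid_ss = (yc ** 2).sum() - beta ** 2 * var_d
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / var_d)
    tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, p


def make_two_sample_stats(
    exposure_expr: ExpressionMatrix,
    exposure_geno: GenotypeMatrix,
    outcome_phenotype: np.ndarray,
    outcome_geno: GenotypeMatrix,
    snp_ids: Sequence[str],
    module_genes: Sequence[str],
    module_label: str = "module_activity",
    binary_outcome: bool = False,
) -> tuple[list[EQTLRecord], list[GWASSummaryRecord]]:
    """Per-SNP summary statistics in each cohort for the listed SNPs.

    Exposure betas: OLS of the module's standardized PC1 activity on dosage
    in cohort 1.  Outcome betas: OLS (or logistic for a binary phenotype) of
    the phenotype on dosage in cohort 2.  Monomorphic SNPs are skipped with
    a log message.
    """
    activity = measured_module_activity(exposure_expr, module_genes)
    exp_cols = {s: i for i, s in enumerate(exposure_geno.snp_ids)}
    out_cols = {s: i for i, s in enumerate(outcome_geno.snp_ids)}
    keep: list[str] = []
    for s in snp_ids:
        de = exposure_geno.dosages[:, exp_cols[s]]
        do = outcome_geno.dosages[:, out_cols[s]]
        if np.var(de) == 0 or np.var(do) == 0:
            logger.info("make_two_sample_stats: skipping monomorphic SNP %s", s)
            continue
        keep.append(s)
    d_exp = exposure_geno.dosages[:, [exp_cols[s] for s in keep]]
    d_out = outcome_geno.dosages[:, [out_cols[s] for s in keep]]

    b_e, se_e, p_e = _per_snp_ols(activity, d_exp)
    if binary_outcome:
        b_o, se_o, p_o = _per_snp_logistic(outcome_phenotype, d_out)
    else:
        b_o, se_o, p_o = _per_snp_ols(np.asarray(outcome_phenotype, float), d_out)

    v_by_id = {v.snp_id: v for v in exposure_geno.variants}
    exposure = [EQTLRecord(v_by_id[s], module_label, float(b), float(se), float(max(p, 1e-300)))
                for s, b, se, p in zip(keep, b_e, se_e, p_e)]
    outcome = [GWASSummaryRecord(v_by_id[s], float(b), float(se), float(max(p, 1e-300)))
               for s, b, se, p in zip(keep, b_o, se_o, p_o)]
    return exposure, outcome


def _per_snp_logistic(y: np.ndarray, dosages: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    betas, ses, ps = [], [], []
    for j in range(dosages.shape[1]):
        X = sm.add_constant(dosages[:, j])
        fit = sm.Logit(y, X).fit(disp=0)
        betas.append(fit.params[1])
        ses.append(fit.bse[1])
        ps.append(fit.pvalues[1])
    return np.array(betas), np.array(ses), np.array(ps)
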