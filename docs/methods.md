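# Methods

This note documents the models implemented in `fetomod`, the synthetic
system they are validated against, the parameter choices that matter, and
the known limits of both.

## The generative model

The generator plants the causal chain the analysis is meant to recover:
genotype → placental module expression → adult outcome, measured in two
disjoint cohorts (the two-sample MR structure; no sample overlap, no
reverse path).

**Genotypes.** Haplotypes are equicorrelated Gaussian latents per LD block
(`z = √ρ·shared + √(1−ρ)·private`, block size 10, ρ = 0.6 by default)
thresholded at the (1 − MAF) normal quantile, MAF ~ Uniform(0.05, 0.5) per
SNP; dosage is the sum of two independent haplotypes. Blocks sit 1 Mb
apart on one chromosome with 1 kb within-block spacing, so clumping
windows behave as on real data. This produces blocky LD without
recombination maps, population structure, or imputation uncertainty.

**Expression.** `X[g,s] = baseline + β_g·d[s, j(g)] + λ_g·F[m(g), s] + ε`,
with per-module standard-normal factors `F`, loadings
λ ~ Uniform(0.6, 0.9) for module genes (0 otherwise), noise sd 1, baseline
8 (so values are effectively positive; the Gaussian model makes a hard
non-negativity constraint impossible, and nothing downstream requires
it). A fraction `eqtl_frac` of each module's genes receives one cis-eQTL
with β ~ Normal(0, eqtl_beta_sd²), optionally sign-restricted
(`eqtl_positive_frac`), one eQTL per LD block while blocks last;
`background_eqtl_frac` extends eQTL coverage to non-module genes,
emulating a transcriptome-wide eQTL resource (needed by random-gene
negative controls).

**Outcome.** Liability `L = γ·M + Σ_pleiotropic δ_j d_j + e`, where `M` is
the target module's genetically determined activity *on the scale of the
standardized PC1 of its expression*. Because module genes are z-scored
before the PC is taken, gene g enters with weight `u_g = λ_g/σ_g`
(σ_g² = λ_g² + β_g²·var(d) + 1), and the standardized PC1 responds to eQTL
SNP j with per-allele slope `u_g β_j/(σ_g‖u‖·sd_t)`. `M` accumulates
exactly those slopes over the true eQTL map, so per-SNP Wald ratios
β_out/β_exp concentrate at γ when the measured exposure is the
standardized, mean-profile-oriented PC1 — the estimation chain only ever
sees observables. Pleiotropic deltas are Normal(0, pleiotropy_sd²),
optionally folded to positive (`pleiotropy_directional`) to create the
classical directional-pleiotropy violation. A binary outcome thresholds L
at the prevalence quantile.

All randomness flows through one `numpy.random.Generator` (PCG64) seeded
from `SimulationParams.seed`; the pipeline expands a global seed into
per-stage substreams via `SeedSequence([seed, stage_index])`.

## Network stage

* **Expression filter**: "expressed" means value > 0; genes kept when
  expressed in strictly more than 90% of samples, then zero-variance genes
  dropped. Sample outliers are flagged when their first merge in an
  average-linkage tree on Euclidean sample distances exceeds
  mean + 2.5 sd of all merge heights. Genes are filtered before outlier
  detection when both are used.
* **Correlation**: biweight midcorrelation with the 9·MAD Tukey weight; a
  vector with MAD = 0 cannot be robustly standardized, so such a pair
  falls back to Pearson (the matrix path substitutes the centred vector
  row-wise). The `maxPOutliers` refinement is not implemented.
* **Adjacency**: signed, `((1 + cor)/2)^β`, β = 14 by default; the
  scale-free criterion bins connectivity into 10 equal-count bins and
  regresses log₁₀(frequency) on log₁₀(mean k), signing R² by the negated
  slope so only decaying laws count. The smallest candidate power reaching
  signed R² ≥ 0.8 wins, else the argmax; a configured power bypasses
  selection.
* **Tree cut**: average linkage on 1 − TOM. TOM dissimilarities compress
  into a narrow band near 1, so the static cut is taken at
  `h_min + 0.99·(h_max − h_min)` — a fraction of the merge-height *range*,
  which is invariant to that compression. Clusters ≥ 30 genes qualify as
  modules only if their mean internal TOM is at least twice the mean TOM
  between the cluster and the rest of the network; the loose clump that
  pure-noise data forms below any cut fails this contrast and goes grey,
  while planted modules exceed it by an order of magnitude (the factor 2
  is a conservative separation margin, not a fitted constant). One
  refinement pass re-cuts a module whose sorted internal merge heights
  contain a gap > 25% of their range (two factors fused in one branch),
  keeping sub-clusters of sufficient size. The cut is a deliberately
  simple stand-in for dynamic tree cutting and is validated by
  planted-module recovery (ARI ≈ 1 at the default conditions), not by
  equivalence to any reference implementation.
* **Eigengenes / merging**: module PC1 of the standardized submatrix,
  unit variance, oriented positively with the module's mean profile;
  merging is iterative (recompute after every merge), threshold r > 0.85,
  ties broken lexicographically, the larger module keeps its name.

## Preservation

Six statistics per module — density: mean off-diagonal signed adjacency,
eigengene variance explained, mean signed kME (all on test data);
connectivity: correlation of intramodular connectivity vectors, of kME
vectors, and of vectorized gene–gene correlations (reference vs test).
Permutations reassign module labels uniformly at random preserving size;
Z = (obs − mean_perm)/sd_perm, Zdensity/Zconnectivity are medians of their
three Zs, Zsummary their mean, classified at the conventional 2/10
thresholds. The test adjacency reuses the reference soft power; genes
absent from the test data are dropped with a log message. Connectivity Zs
run much smaller than density Zs under this scheme: a random gene set
already shows reproducible connectivity (its member genes keep their
hub-ness across datasets), so the null is not centred at zero for those
statistics — Zsummary classification is dominated by density, which is the
behaviour the 2/10 thresholds assume. The published composite also
includes separability statistics; they are not implemented.

## Expression PGS

SNP→gene mapping is gene-body containment (1-based inclusive; window
configurable, default 0). Clumping is greedy by ascending p (ties by SNP
id): accept, prune neighbours within 250 kb at dosage r² ≥ 0.2, repeat;
SNPs absent from the reference panel pass through with a warning. A SNP
that is an eQTL for two listed genes contributes once with the smaller-p
record. Scores are Σ weight × effect-allele dosage with allele
orientation checked per SNP (swapped alleles flip the dosage; other
mismatches drop the SNP); missing dosages are mean-imputed (≡ 2×EAF) by
default, with `zero` and `drop` alternatives.

Negative controls reproduce the published design: a size-matched other
module, random gene lists of the module's size, and the module itself
under another tissue's weights. The random-gene universe excludes the
target module: at desk scale (hundreds of genes) a uniform draw would put
~10% of the target module inside every "negative" control — a leak the
31k-gene universe of a real study does not have.

**Power arithmetic.** The PGS explains a fraction
`k·E[β²]·var(d)/m²` of the module-score variance (k eQTLs among m module
genes; the score variance itself is dominated by the shared factor,
λ̄² ≈ 0.56). With k = 9, m = 30 and |β| = 0.3 that is ~6×10⁻⁴/0.6 ≈ 0.1%
(r ≈ 0.025): a regression at n = 500 has ~7% power, and no module size
changes the conclusion because the share scales as 1/m². The
corresponding calibration test is therefore expected to fail and is kept
as an honest record of that arithmetic. With strong placental-grade cis-eQTLs
(full module coverage, β sd = 2 — per-gene genetic share ≈ 50%,
consistent with the strong PGS→ssGSEA correlations reported from real
placental data at n ≈ 42) the same design reaches ≥ 88% power at n = 500.

## ssGSEA and cell-level scores

Per sample, genes are ranked by expression (average ranks for ties —
integer-rank variants differ, hence the explicit choice) and the
enrichment score is the summed running difference between the weighted
in-set CDF (weight `rank^τ`, τ = 0.25) and the uniform out-of-set CDF.
Range normalization (divide all scores by max − min) is on by default;
both τ and normalization are exposed because the upstream publication
names only the implementing package. Scores are invariant to monotone
transforms of a sample's profile by construction.

The cell-level score is the bin-matched control difference: genes binned
into 24 equal-count bins of mean expression, 100 control genes per set
gene drawn from its bin (without replacement when the bin allows), score =
mean(set) − mean(controls) per cell. Group comparisons: two-sided
Wilcoxon rank-sum (normal approximation with tie correction) for two
groups; Kruskal–Wallis plus pairwise Wilcoxon against a designated
reference with BH correction otherwise.

## PheWAS

Outcome typing is a deliberate reduction of the PHESANT tree: two distinct
values → binary (logistic), integer-valued with ≤ 20 levels → ordinal
(proportional-odds logit), else continuous (OLS); constant outcomes are
skipped, unordered categoricals are not fitted, and choosing among
repeated measurements is the caller's responsibility. Covariates expand
categoricals one-hot against the most frequent level. Fits are
complete-case per outcome; non-convergence or suspected separation
(|coef| > 30) excludes the outcome from the BH batch with a flag. The
Miami table carries sign(β)·(−log₁₀ p) and the FDR threshold line (largest
raw p rejected by BH).

## Mendelian randomization

Harmonization intersects SNPs, resolves swapped and complementary-strand
alleles (negating the outcome beta when flipped), drops everything else,
and drops palindromic SNPs unconditionally — no frequency-based rescue, in
line with "ambiguous SNPs removed". Estimators: fixed-effects IVW
(primary; a multiplicative random-effects variant is available but
non-default), weighted median (half-step interpolated weighted quantile,
parametric bootstrap SE with 1000 draws, seeded), MR-Egger (WLS with
intercept after forcing exposure betas non-negative; t inference with
n − 2 df). Wald-ratio SEs are first order (se_out/|β_exp|); Q uses the
IVW parameterization with df = n − 1. Single-SNP and leave-one-out tables
round out the sensitivity report.

## Enrichment and connectivity

Overlap tests are one-sided hypergeometric over an explicit universe
(default: the filtered expressed-gene list), odds ratios take the Haldane
0.5 correction when a cell is empty, batches are BH-corrected. The MI
network uses the plug-in estimator on 5 equal-frequency bins (nats); the
edge threshold is the (1 − α) quantile of MI between randomly chosen
row-permuted gene pairs (default α = 0.05, 100 permutations; calibration
measurements use 400 to tighten the quantile estimate). The DPI pass
removes, within every fully significant triangle, the edge weaker than
both others by factor (1 − dpi_eps), dpi_eps = 0 by default; connectivity
is the degree of the pruned unweighted graph.

## Benchmark conditions (fetomod.benchmarks)

* `recovery`: the generator defaults — 2000 genes, modules
  100/100/80/60/50, loadings 0.6–0.9, noise 1, 1000 SNPs, n = 1000.
* `preservation`: 600 genes, modules 80/60, two cohorts of 300, 100
  permutations.
* `pgs`: 300 genes, two 30-gene modules, 1000 SNPs in 100 LD blocks
  (fewer blocks would put control eQTLs in LD with target eQTLs and leak
  signal into the negative controls), n = 500.
* `mr`: a 15-gene target module, every gene one positively oriented
  cis-eQTL with β sd = 2, two cohorts of 2000, γ = −0.1. The per-SNP
  slope on module activity is `λβ/(σ²·…)` and saturates in β: one cis-SNP
  can explain at most about half of one gene and hence a bounded share of
  a 15-gene activity score, capping mean instrument F near 9 at n = 2000.
  γ is chosen small so the resulting ~1/F weak-instrument dilution stays
  well below the IVW standard error — the regime the published protective
  effects (|γ| ≈ 0.009) occupy. Measured under these conditions: IVW 95%
  CI coverage ≈ 0.93, Egger intercept type-I ≈ 0.05, mean Q/df ≈ 0.98,
  and the weighted median beats IVW in absolute bias when 40% of
  instruments carry directional pleiotropy.
* `demo` (analysis drivers): 1000 genes, modules 30/80/60 with full
  strong-eQTL coverage, two cohorts of 2000, γ = −0.15 — conditions under
  which a *single* run of every stage is informative. At the recovery
  defaults the genetic stages are deliberately underpowered (instrument
  F ≈ 0.02) and only their Monte-Carlo calibrations are meaningful.

## What the generator does not emulate

Count noise and library-size effects (expression is Gaussian around a
baseline, not RPKM from reads), realistic LD decay and recombination,
population structure and relatedness, cell-type composition, multiple
cis-SNPs per gene, reverse causation, and sample overlap between cohorts.
Tests passing on this system show the estimators are implemented
correctly and calibrated under their own assumptions; they do not show
robustness to those real-data complications.

## Numerical choices and degenerate inputs

Ties in clumping order break by SNP id; module naming is size-descending
with first-gene-id tie-break, so partitions are gene-order invariant up to
renaming. Permutation SDs of zero yield ±∞ Z with a degeneracy flag.
Monomorphic SNPs are skipped (logged) in summary-statistic computation;
constant genes are dropped before MI estimation; eigengenes require ≥ 2
genes. Exact p-values are floored at 1e-300 before logs. Weighted-median
estimation drops β_exp = 0 SNPs. All output tables are TSV (6 significant
digits) with JSON sidecars recording config and seed.
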