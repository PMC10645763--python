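"""Frozen study conditions for the package's calibration benchmarks.

Every Monte-Carlo claim the test suite and the acceptance script make runs
under the parameter sets defined here, so the conditions are stated once
and shared.  Rationale for the choices lives in ``docs/methods.md``; in
short:

* ``recovery`` — the generator's defaults (2000 genes, five planted modules
  of 100/100/80/60/50 genes, loadings 0.6-0.9, unit noise): the module-
  detection stress test.
* ``mr`` — a 15-gene target module in which every gene has one strong
  cis-eQTL (effect-size sd 2 expression-sd per allele, near the per-SNP
  information optimum given unit gene noise) and a small causal effect
  gamma = -0.1 on the outcome, measured in two independent cohorts of
  2000.  Instrument strength (mean F ~ 9) is capped by the generator's
  physics: one cis-SNP can explain at most about half of one gene, hence a
  small share of a multi-gene activity score.
* ``pgs`` — two 30-gene modules plus background eQTLs in a 300-gene,
  500-sample cohort; the *stated-effects* variant uses per-gene eQTL
  effect sd 0.3, the *strong-eQTL* variant sd 2.0 with full module
  coverage.
"""

from __future__ import annotations

import numpy as np

from . import mr as mr_mod
from . import pgs as pgs_mod
from .io_formats import EQTLRecord, GeneSetCollection, GenotypeMatrix
from .scoring import ssgsea
from .synthetic import (SimulationParams, SimulationTruth, make_two_sample_stats,
                        simulate_cohort, simulate_outcome)


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

def recovery_params(seed: int) -> SimulationParams:
    """Default generator conditions for planted-module recovery."""
    return SimulationParams(seed=seed)


def mr_params(seed: int, gamma: float = -0.1, pleiotropy_frac: float = 0.0,
              pleiotropy_sd: float = 0.1,
              pleiotropy_directional: bool = True) -> SimulationParams:
    """Two-sample MR benchmark: 15 strong, positively oriented instruments."""
    return SimulationParams(
        seed=seed, n_exposure_samples=2000, n_outcome_samples=2000,
        n_genes=100, module_sizes=(15,), n_snps=300,
        eqtl_frac=1.0, eqtl_beta_sd=2.0, eqtl_positive_frac=1.0,
        gamma=gamma, pleiotropy_frac=pleiotropy_frac,
        pleiotropy_sd=pleiotropy_sd,
        pleiotropy_directional=pleiotropy_directional)


def pgs_params(seed: int, eqtl_frac: float = 0.3,
               eqtl_beta_sd: float = 0.3) -> SimulationParams:
    """PGS-specificity benchmark cohort (Fig-1c-style design).

    1000 SNPs in 100 LD blocks keep the ~100 planted eQTLs in distinct
    blocks; with fewer blocks, control eQTLs would share LD with target
    eQTLs and leak true signal into the negative controls — an artifact of
    scale, not of the design.
    """
    return SimulationParams(
        seed=seed, n_exposure_samples=500, n_genes=300,
        module_sizes=(30, 30), n_snps=1000, eqtl_frac=eqtl_frac,
        background_eqtl_frac=0.3, eqtl_beta_sd=eqtl_beta_sd)


def demo_params(seed: int) -> SimulationParams:
    """End-to-end demonstration system for the analysis drivers.

    Strong placental-grade cis-eQTLs (full coverage of a compact 30-gene target
    module, effect sd 2) and two cohorts of 2000, so every stage of the
    chain — detection, preservation, PGS validation, pheWAS, MR — is
    informative in a single run.  At the recovery defaults (per-gene eQTL
    effect sd 0.3) the genetic stages are deliberately underpowered and
    only their Monte-Carlo calibrations are meaningful.
    """
    return SimulationParams(
        seed=seed, n_genes=1000, module_sizes=(30, 80, 60), n_snps=2000,
        n_exposure_samples=2000, n_outcome_samples=2000,
        eqtl_frac=1.0, background_eqtl_frac=0.2, eqtl_beta_sd=2.0,
        gamma=-0.15)


def preservation_params(seed: int) -> SimulationParams:
    """Reference/replicate cohorts for the Zsummary calibration."""
    return SimulationParams(seed=seed, n_genes=600, module_sizes=(80, 60),
                            n_snps=200, n_exposure_samples=300)


# ---------------------------------------------------------------------------
# replicate runners
# ---------------------------------------------------------------------------

def true_eqtl_records(truth: SimulationTruth,
                      geno: GenotypeMatrix) -> list[EQTLRecord]:
    """The eQTL resource implied by the planted truth (nominal se/p)."""
    v_by = {v.snp_id: v for v in geno.variants}
    return [EQTLRecord(v_by[s], gene, truth.eqtl_beta[s], 0.05, 1e-8)
            for gene, s in truth.eqtl_snp_of_gene.items()]


def mr_replicate(params: SimulationParams) -> tuple[mr_mod.HarmonizedInstruments,
                                                    SimulationTruth]:
    """Simulate both cohorts, compute summary stats, harmonize."""
    rng = np.random.default_rng(params.seed)
    geno_exp, expr_exp, truth = simulate_cohort(params, rng, "exp")
    geno_out, _, _ = simulate_cohort(params, rng, "out",
                                     n_samples=params.n_outcome_samples,
                                     truth=truth)
    phenotype = simulate_outcome(truth, geno_out, params, rng)
    exposure, outcome = make_two_sample_stats(
        expr_exp, geno_exp, phenotype, geno_out, truth.instrument_snps(),
        truth.module_genes(truth.target_module),
        binary_outcome=params.binary_outcome)
    return mr_mod.harmonize(exposure, outcome), truth


def pgs_validation_sim(params: SimulationParams) -> dict[str, float]:
    """One PGS-specificity replicate: target PGS plus three negative controls
    regressed on the target module's ssGSEA score.

    Returns the regression beta and p for the target score and the p-values
    of the size-matched-module, random-gene and alternative-tissue
    controls.  The random-gene universe excludes the target module so the
    control carries no true signal.
    """
    rng = np.random.default_rng(params.seed)
    geno, expr, truth = simulate_cohort(params, rng)
    records = true_eqtl_records(truth, geno)
    target = truth.module_genes(truth.target_module)
    score = ssgsea(expr, GeneSetCollection({"target": target})
                   ).scores["target"].to_numpy()

    out: dict[str, float] = {}
    w = pgs_mod.weights_from_eqtls(records, target, geno,
                                   provenance=truth.target_module)
    rep = pgs_mod.validate_pgs(pgs_mod.build_pgs(geno, w), score)
    out["target_beta"], out["target_p"] = rep.beta, rep.p

    other = [m for m in set(truth.module_of_gene.values())
             if m not in ("grey", truth.target_module)][0]
    w2 = pgs_mod.negative_control_pgs(
        "size_matched_module", len(target), params.seed, records,
        module_genes=truth.module_genes(other), reference=geno)
    out["control_module_p"] = pgs_mod.validate_pgs(
        pgs_mod.build_pgs(geno, w2), score).p

    universe = [g for g in expr.gene_ids if g not in set(target)]
    w3 = pgs_mod.negative_control_pgs(
        "random_genes", len(target), params.seed + 1, records,
        universe=universe, reference=geno)
    if w3.entries:
        out["control_random_p"] = pgs_mod.validate_pgs(
            pgs_mod.build_pgs(geno, w3), score).p

    used = set(truth.eqtl_beta)
    free = [v for v in geno.variants if v.snp_id not in used]
    rng_alt = np.random.default_rng(params.seed + 2)
    alt = [EQTLRecord(free[i], gene,
                      float(rng_alt.normal(0.0, params.eqtl_beta_sd)),
                      0.05, 1e-8)
           for i, gene in enumerate(target)]
    w4 = pgs_mod.negative_control_pgs(
        "alternative_tissue_weights", len(target), params.seed + 2, alt,
        module_genes=target, reference=geno)
    out["control_alt_p"] = pgs_mod.validate_pgs(
        pgs_mod.build_pgs(geno, w4), score).p
    return out
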