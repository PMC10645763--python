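"""Configuration-driven orchestration of the full synthetic analysis chain.

Stage order mirrors the analysis narrative: simulate two cohorts ->
co-expression network -> module preservation in a replicate ->
eQTL-weighted PGS with negative controls -> ssGSEA validation -> pheWAS ->
two-sample MR with sensitivity analyses -> overlap enrichment and
mutual-information connectivity.  Every stage writes TSV artifacts plus a
manifest entry (input/output hashes, wall-clock, seed) so deterministic
stages reproduce byte-identical outputs and partial runs are resumable.

One global seed is expanded into per-stage substreams with
``numpy.random.SeedSequence(global_seed, stage_index)`` so each stage is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, enrichment, mr, pgs, phewas, preservation, scoring
from .io_formats import (AnalysisConfig, ExpressionMatrix, GeneSetCollection,
                         write_dosages, write_expression, write_gmt, write_table)
from .synthetic import (SimulationParams, make_two_sample_stats,
                        simulate_cohort, simulate_outcome)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "network", "preserve", "pgs", "score",
          "phewas", "mr", "enrich", "connectivity")

# stage -> stages whose artifacts it consumes
_DEPENDS = {
    "network": ("simulate",),
    "preserve": ("simulate", "network"),
    "pgs": ("simulate", "network"),
    "score": ("simulate", "network", "pgs"),
    "phewas": ("simulate", "pgs"),
    "mr": ("simulate", "network"),
    "enrich": ("simulate", "network"),
    "connectivity": ("simulate", "network"),
}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([global_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig, sim_params: SimulationParams,
                 out_dir: str | Path, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the enabled stages in order; returns the manifest dict.

    A stage that needs an earlier stage's in-memory artifacts raises a
    dependency error when that stage is disabled.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in stages]
    for s in enabled:
        missing = [d for d in _DEPENDS.get(s, ()) if d not in enabled]
        if missing:
            raise ValueError(f"stage {s!r} requires disabled stage(s) {missing}")

    manifest: dict = {"config": config.to_dict(),
                      "sim_params": sim_params.__dict__ | {
                          "module_sizes": list(sim_params.module_sizes),
                          "maf_range": list(sim_params.maf_range),
                          "loading_range": list(sim_params.loading_range)},
                      "stages": {}}
    state: dict = {}
    manifest_path = out / "manifest.json"
    for s in enabled:
        t0 = time.perf_counter()
        written = _RUNNERS[s](config, sim_params, out, state)
        manifest["stages"][s] = {
            "seed": stage_seed(sim_params.seed, s),
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _hash_file(p) for p in written},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stage runners (each returns the files it wrote)
# ---------------------------------------------------------------------------

def _run_simulate(config, params, out, state):
    rng = np.random.default_rng(stage_seed(params.seed, "simulate"))
    geno_exp, expr_exp, truth = simulate_cohort(params, rng, "exp")
    geno_out, _, _ = simulate_cohort(params, rng, "out",
                                     n_samples=params.n_outcome_samples,
                                     truth=truth)
    phenotype = simulate_outcome(truth, geno_out, params, rng)
    state.update(geno_exp=geno_exp, expr_exp=expr_exp, truth=truth,
                 geno_out=geno_out, phenotype=phenotype)
    write_expression(expr_exp, out / "expression.tsv")
    write_dosages(geno_exp, out / "dosages_exposure.tsv", out / "variants.tsv")
    planted = GeneSetCollection({m: truth.module_genes(m)
                                 for m in set(truth.module_of_gene.values())
                                 if m != "grey"})
    write_gmt(planted, out / "planted_modules.gmt")
    pheno = pd.DataFrame({"sample_id": geno_out.sample_ids, "phenotype": phenotype})
    write_table(pheno, out / "phenotype_outcome.tsv",
                sidecar={"seed": params.seed, "gamma": params.gamma})
    return [out / n for n in ("expression.tsv", "dosages_exposure.tsv",
                              "variants.tsv", "planted_modules.gmt",
                              "phenotype_outcome.tsv")]


def _run_network(config, params, out, state):
    net_params = coexpression.NetworkParams(
        soft_power=config.soft_power, signed=config.signed,
        min_module_size=config.min_module_size,
        merge_cor_threshold=config.merge_cor_threshold,
        scale_free_target_r2=config.scale_free_target_r2,
        expressed_fraction=config.expressed_fraction,
        cut_height_frac=config.cut_height_frac, gap_frac=config.gap_frac)
    filtered, tom_m, part, em = coexpression.run_network(state["expr_exp"], net_params)
    state.update(filtered=filtered, partition=part, eigengenes=em)
    write_table(pd.DataFrame({"gene": list(part.labels),
                              "module": list(part.labels.values())}),
                out / "modules.tsv", sidecar={"params": net_params.__dict__})
    if part.modules():
        write_gmt(GeneSetCollection({m: part.module_genes(m) for m in part.modules()}),
                  out / "modules.gmt")
    eg = pd.DataFrame(em.eigengenes, index=em.sample_ids)
    eg.insert(0, "sample_id", em.sample_ids)
    write_table(eg, out / "eigengenes.tsv")
    return [out / "modules.tsv", out / "eigengenes.tsv"]


def _run_preserve(config, params, out, state):
    rng_seed = stage_seed(params.seed, "preserve")
    rng = np.random.default_rng(rng_seed)
    _, expr_rep, _ = simulate_cohort(params, rng, "rep",
                                     n_samples=params.n_exposure_samples,
                                     truth=state["truth"])
    res = preservation.module_preservation(
        state["filtered"], state["partition"], expr_rep,
        n_perm=config.n_permutations, seed=rng_seed,
        soft_power=config.soft_power)
    rows = [{"module": m.module, "z_density": m.z_density,
             "z_connectivity": m.z_connectivity, "z_summary": m.z_summary,
             "class": m.classification} for m in res.modules.values()]
    write_table(pd.DataFrame(rows), out / "preservation.tsv",
                sidecar={"n_perm": res.n_permutations, "seed": res.seed})
    state["preservation"] = res
    return [out / "preservation.tsv"]


def _true_eqtl_records(state, params):
    """eQTL table implied by the simulation truth (beta = planted effect)."""
    from .io_formats import EQTLRecord

    truth, geno = state["truth"], state["geno_exp"]
    v_by_id = {v.snp_id: v for v in geno.variants}
    records = []
    for gene, snp in truth.eqtl_snp_of_gene.items():
        records.append(EQTLRecord(v_by_id[snp], gene,
                                  truth.eqtl_beta[snp], 0.05, 1e-8))
    return records


def _run_pgs(config, params, out, state):
    truth = state["truth"]
    eqtls = _true_eqtl_records(state, params)
    target_genes = truth.module_genes(truth.target_module)
    weights = pgs.weights_from_eqtls(eqtls, target_genes, state["geno_exp"],
                                     config.clump_r2, config.clump_window_kb,
                                     provenance=truth.target_module)
    vector = pgs.build_pgs(state["geno_exp"], weights, config.missing_policy)
    state.update(pgs_weights=weights, pgs_vector=vector, eqtl_records=eqtls)
    write_table(pd.DataFrame({"sample_id": vector.sample_ids,
                              "score": vector.scores}),
                out / "pgs_scores.tsv",
                sidecar={"module": truth.target_module,
                         "n_snps": vector.n_snps_used})
    return [out / "pgs_scores.tsv"]


def _run_score(config, params, out, state):
    truth = state["truth"]
    sets = GeneSetCollection({truth.target_module:
                              truth.module_genes(truth.target_module)})
    table = scoring.ssgsea(state["expr_exp"], sets,
                           tau=config.ssgsea_tau,
                           normalize=config.ssgsea_normalize)
    report = pgs.validate_pgs(state["pgs_vector"],
                              table.scores[truth.target_module].to_numpy())
    state.update(ssgsea_table=table, pgs_validation=report)
    df = table.scores.reset_index(names="sample_id")
    write_table(df, out / "ssgsea_scores.tsv",
                sidecar={"validation": {"beta": report.beta, "se": report.se,
                                        "p": report.p, "n": report.n}})
    return [out / "ssgsea_scores.tsv"]


def _run_phewas(config, params, out, state):
    rng = np.random.default_rng(stage_seed(params.seed, "phewas"))
    vector = state["pgs_vector"]
    n = len(vector.sample_ids)
    outcomes = pd.DataFrame(
        rng.standard_normal((n, 20)),
        columns=[f"null_{k:02d}" for k in range(20)],
        index=vector.sample_ids)
    z = (vector.scores - vector.scores.mean()) / (vector.scores.std() or 1.0)
    outcomes["planted"] = 0.3 * z + rng.standard_normal(n)
    res = phewas.run_phewas(pd.Series(vector.scores, index=vector.sample_ids),
                            outcomes, fdr_level=config.fdr_level)
    write_table(res.table, out / "phewas.tsv")
    state["phewas"] = res
    return [out / "phewas.tsv"]


def _run_mr(config, params, out, state):
    truth = state["truth"]
    snps = truth.instrument_snps()
    exposure, outcome = make_two_sample_stats(
        state["filtered"], state["geno_exp"], state["phenotype"],
        state["geno_out"], snps, truth.module_genes(truth.target_module),
        binary_outcome=params.binary_outcome)
    h = mr.harmonize(exposure, outcome)
    ivw = mr.mr_ivw(h)
    rows = [ivw]
    if len(h) >= 3:
        rows.append(mr.mr_weighted_median(h, config.wm_bootstrap,
                                          stage_seed(params.seed, "mr")))
        slope, intercept = mr.mr_egger(h)
        rows.extend([slope, intercept])
    sens = mr.sensitivity(h, ivw)
    est = pd.DataFrame([{"method": e.method, "estimate": e.estimate,
                         "se": e.se, "p": e.p, "n_snps": e.n_snps}
                        for e in rows])
    write_table(est, out / "mr_estimates.tsv",
                sidecar={"cochran_q": sens.cochran_q, "q_df": sens.df,
                         "q_p": sens.q_p, "gamma_true": truth.gamma})
    write_table(sens.single_snp, out / "mr_single_snp.tsv")
    state.update(mr_harmonized=h, mr_ivw=ivw, mr_sensitivity=sens)
    return [out / "mr_estimates.tsv", out / "mr_single_snp.tsv"]


def _run_enrich(config, params, out, state):
    truth = state["truth"]
    rng = np.random.default_rng(stage_seed(params.seed, "enrich"))
    universe = set(state["filtered"].gene_ids)
    target = set(truth.module_genes(truth.target_module)) & universe
    # emulated DEG lists: one drawn mostly from the target module, one random
    inside = rng.choice(sorted(target), size=min(30, len(target)), replace=False)
    random_genes = rng.choice(sorted(universe), size=50, replace=False)
    tests = enrichment.overlap_tests(
        target, {"module_derived": set(inside), "random": set(random_genes)},
        universe)
    write_table(tests, out / "enrichment.tsv")
    state["enrichment"] = tests
    return [out / "enrichment.tsv"]


def _run_connectivity(config, params, out, state):
    truth = state["truth"]
    genes = [g for g in truth.module_genes(truth.target_module)
             if g in state["filtered"].gene_ids]
    sub = state["filtered"].subset_genes(genes)
    net = enrichment.aracne_network(
        sub.values, genes, n_bins=config.mi_bins,
        n_perm=config.mi_permutations, alpha=config.mi_alpha,
        dpi_eps=config.dpi_eps,
        seed=stage_seed(params.seed, "connectivity"))
    write_table(net.degree.reset_index().rename(columns={"index": "gene"}),
                out / "connectivity.tsv",
                sidecar={"threshold": net.threshold})
    state["mi_network"] = net
    return [out / "connectivity.tsv"]


_RUNNERS = {
    "simulate": _run_simulate,
    "network": _run_network,
    "preserve": _run_preserve,
    "pgs": _run_pgs,
    "score": _run_score,
    "phewas": _run_phewas,
    "mr": _run_mr,
    "enrich": _run_enrich,
    "connectivity": _run_connectivity,
}
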