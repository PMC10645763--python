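"""Permutation Zsummary module-preservation statistics.

Given a module partition learned in a reference expression dataset and an
independent test dataset, six statistics quantify how well each module's
density and connectivity pattern reproduces:

density (test data only)
    meanAdj            mean off-diagonal signed adjacency among module genes
    propVarExplained   variance explained by the test-data eigengene
    meanSignedKME      mean correlation of module genes with that eigengene

connectivity (reference vs test)
    cor.kIM            correlation of intramodular connectivity vectors
    cor.kME            correlation of module-membership (kME) vectors
    cor.cor            correlation of vectorized gene-gene correlations

Each statistic is standardized against its permutation null (module labels
reassigned uniformly at random, preserving module size), giving a Z score;
``Zdensity`` and ``Zconnectivity`` are the medians of their three Zs and
``Zsummary`` their mean.  Conventional thresholds: < 2 no evidence, 2-10
weak-to-moderate, > 10 strong preservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coexpression import GREY, ModulePartition, bicor_matrix
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

DENSITY_STATS = ("meanAdj", "propVarExplained", "meanSignedKME")
CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.cor")


@dataclass
class ModulePreservation:
    module: str
    z_density: float
    z_connectivity: float
    z_summary: float
    classification: str
    observed: dict[str, float]
    z_scores: dict[str, float]
    degenerate_null: bool  # any permutation sd was zero


@dataclass
class PreservationResult:
    modules: dict[str, ModulePreservation]
    n_permutations: int
    seed: int


def classify_zsummary(z: float) -> str:
    if z < 2:
        return "none"
    if z <= 10:
        return "weak-moderate"
    return "strong"


def module_preservation(ref_expr: ExpressionMatrix,
                        partition: ModulePartition,
                        test_expr: ExpressionMatrix,
                        n_perm: int = 100,
                        seed: int = 0,
                        soft_power: int = 14,
                        min_module_size: int = 10) -> PreservationResult:
    """Permutation Z statistics for every non-grey module of ``partition``.

    Genes absent from the test dataset are dropped from their module with a
    log message; the permutation universe is the gene set shared by both
    datasets.  The test adjacency reuses the reference soft power.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable null")
    shared = [g for g in ref_expr.gene_ids if g in set(test_expr.gene_ids)]
    if len(shared) < min_module_size:
        raise ValueError("too few shared genes between datasets")
    ref = ref_expr.subset_genes(shared)
    test = test_expr.subset_genes(shared)
    cor_ref = bicor_matrix(ref.values)
    cor_test = bicor_matrix(test.values)
    adj_test = ((1.0 + cor_test) / 2.0) ** soft_power
    np.fill_diagonal(adj_test, 0.0)

    idx = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)
    out: dict[str, ModulePreservation] = {}
    for module in partition.modules():
        genes = [g for g in partition.module_genes(module) if g in idx]
        dropped = len(partition.module_genes(module)) - len(genes)
        if dropped:
            logger.info("module %s: %d genes absent from test data", module, dropped)
        if len(genes) < min_module_size:
            logger.warning("module %s: too few shared genes, skipped", module)
            continue
        rows = np.array([idx[g] for g in genes])
        obs = _module_stats(rows, ref.values, test.values,
                            cor_ref, cor_test, adj_test)
        null = np.empty((n_perm, len(obs)))
        for p in range(n_perm):
            perm_rows = rng.choice(len(shared), size=len(rows), replace=False)
            null[p] = _module_stats(perm_rows, ref.values, test.values,
                                    cor_ref, cor_test, adj_test)
        mean = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        degenerate = bool((sd == 0).any())
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (obs - mean) / sd,
                         np.sign(obs - mean) * np.inf)
        names = DENSITY_STATS + CONNECTIVITY_STATS
        z_map = dict(zip(names, z))
        z_density = float(np.median([z_map[s] for s in DENSITY_STATS]))
        z_connectivity = float(np.median([z_map[s] for s in CONNECTIVITY_STATS]))
        z_summary = (z_density + z_connectivity) / 2.0
        out[module] = ModulePreservation(
            module, z_density, z_connectivity, z_summary,
            classify_zsummary(z_summary),
            dict(zip(names, obs)), z_map, degenerate)
    return PreservationResult(out, n_perm, seed)


def _module_stats(rows: np.ndarray, ref_values: np.ndarray,
                  test_values: np.ndarray, cor_ref: np.ndarray,
                  cor_test: np.ndarray, adj_test: np.ndarray) -> np.ndarray:
    m = len(rows)
    sub_adj = adj_test[np.ix_(rows, rows)]
    mean_adj = sub_adj.sum() / (m * (m - 1))

    eg_test, ve_test = _pc1(test_values[rows])
    eg_ref, _ = _pc1(ref_values[rows])
    kme_test = _cor_with_vector(test_values[rows], eg_test)
    kme_ref = _cor_with_vector(ref_values[rows], eg_ref)
    mean_signed_kme = float(kme_test.mean())

    sub_ref = cor_ref[np.ix_(rows, rows)]
    sub_test = cor_test[np.ix_(rows, rows)]
    kim_ref = sub_ref.sum(axis=1) - 1.0
    kim_test = sub_test.sum(axis=1) - 1.0
    iu = np.triu_indices(m, k=1)
    return np.array([
        mean_adj, ve_test, mean_signed_kme,
        _safe_cor(kim_ref, kim_test),
        _safe_cor(kme_ref, kme_test),
        _safe_cor(sub_ref[iu], sub_test[iu]),
    ])


def _pc1(values: np.ndarray) -> tuple[np.ndarray, float]:
    z = values - values.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    if np.corrcoef(pc1, values.mean(axis=0))[0, 1] < 0:
        pc1 = -pc1
    return pc1, float(s[0] ** 2 / (s ** 2).sum())


def _cor_with_vector(values: np.ndarray, v: np.ndarray) -> np.ndarray:
    zc = values - values.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(zc, axis=1) * np.linalg.norm(vc)
    denom[denom == 0] = np.nan
    return zc @ vc / denom


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
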