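"""Gene-set overlap enrichment and mutual-information connectivity.

``overlap_test`` is the classic 2x2 Fisher / hypergeometric enrichment of
two gene sets inside a declared universe.  ``aracne_network`` builds an
unweighted association network from pairwise mutual information (plug-in
estimator on equal-frequency bins), keeps edges exceeding a permutation
significance threshold, and prunes indirect edges with the data processing
inequality: in any significant triangle the weakest edge is an indirect
association and is removed.  Per-gene connectivity is the degree in the
pruned graph; group differences in connectivity are compared with
Kruskal-Wallis plus pairwise Wilcoxon tests against a reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multiple_testing import bh_qvalues

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# overlap enrichment
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    odds_ratio: float
    p: float
    q: float | None = None


def overlap_test(set_a: set[str], set_b: set[str],
                 universe: set[str]) -> OverlapResult:
    """One-sided (greater) hypergeometric overlap test over a universe.

    The sample odds ratio uses the Haldane 0.5 correction when any cell of
    the 2x2 table is zero.
    """
    if not universe:
        raise ValueError("universe is empty")
    a_set = set_a & universe
    b_set = set_b & universe
    k = len(a_set & b_set)
    a, b = k, len(a_set) - k
    c = len(b_set) - k
    d = len(universe) - a - b - c
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a_set), len(b_set)))
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return OverlapResult(k, len(a_set), len(b_set), len(universe),
                         float(a2 * d2 / (b2 * c2)), min(max(p, 0.0), 1.0))


def overlap_tests(module: set[str], gene_lists: dict[str, set[str]],
                  universe: set[str]) -> pd.DataFrame:
    """Batch of overlap tests of one module against many lists, BH-corrected."""
    rows = []
    for name, genes in gene_lists.items():
        r = overlap_test(module, genes, universe)
        rows.append({"list": name, "overlap": r.overlap, "size_list": r.size_b,
                     "size_module": r.size_a, "universe": r.universe,
                     "odds_ratio": r.odds_ratio, "p": r.p})
    out = pd.DataFrame(rows)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# ARACNE-style mutual-information network
# ---------------------------------------------------------------------------

@dataclass
class MINetwork:
    gene_ids: list[str]
    mi: np.ndarray                  # symmetric, non-negative, nats
    significant: np.ndarray         # boolean adjacency before DPI
    retained: np.ndarray            # boolean adjacency after DPI
    threshold: float
    degree: pd.Series               # connectivity in the pruned graph


def _discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene (rows), ties broken by order."""
    n = values.shape[1]
    ranks = np.argsort(np.argsort(values, axis=1, kind="stable"), axis=1)
    return (ranks * n_bins // n).astype(np.int64)


def _mutual_information(bi: np.ndarray, bj: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(bi * n_bins + bj, minlength=n_bins * n_bins).astype(float)
    joint /= joint.sum()
    pi = joint.reshape(n_bins, n_bins).sum(axis=1)
    pj = joint.reshape(n_bins, n_bins).sum(axis=0)
    outer = np.outer(pi, pj).ravel()
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())


def aracne_network(expr_values: np.ndarray, gene_ids: list[str],
                   n_bins: int = 5, n_perm: int = 100, alpha: float = 0.05,
                   dpi_eps: float = 0.0, seed: int = 0) -> MINetwork:
    """Mutual-information network with permutation threshold and DPI pruning.

    ``expr_values`` is genes x samples.  Constant genes are dropped with a
    log message.  The significance threshold is the (1 - alpha) quantile of
    mutual information between randomly chosen gene pairs with one row
    permuted (n_perm draws).  DPI removes edge (i, j) from a fully
    significant triangle when ``MI_ij < min(MI_ik, MI_kj) * (1 - dpi_eps)``.
    """
    values = np.asarray(expr_values, float)
    if values.shape[1] < 20:
        logger.warning("aracne_network: fewer than 20 samples; MI estimates are noisy")
    keep = values.std(axis=1) > 0
    if (~keep).any():
        logger.info("aracne_network: dropped %d constant genes", int((~keep).sum()))
    values = values[keep]
    ids = [g for g, k in zip(gene_ids, keep) if k]
    p_genes = len(ids)
    bins = _discretize(values, n_bins)

    mi = np.zeros((p_genes, p_genes))
    for i in range(p_genes):
        for j in range(i + 1, p_genes):
            mi[i, j] = mi[j, i] = _mutual_information(bins[i], bins[j], n_bins)
        mi[i, i] = _mutual_information(bins[i], bins[i], n_bins)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        i, j = rng.choice(p_genes, size=2, replace=False)
        perm = rng.permutation(bins[j])
        null[b] = _mutual_information(bins[i], perm, n_bins)
    threshold = float(np.quantile(null, 1.0 - alpha))

    significant = mi > threshold
    np.fill_diagonal(significant, False)

    retained = significant.copy()
    to_remove: set[tuple[int, int]] = set()
    for i in range(p_genes):
        for j in range(i + 1, p_genes):
            if not significant[i, j]:
                continue
            partners = np.flatnonzero(significant[i] & significant[j])
            for k in partners:
                if mi[i, j] < min(mi[i, k], mi[k, j]) * (1.0 - dpi_eps):
                    to_remove.add((i, j))
                    break
    for i, j in to_remove:
        retained[i, j] = retained[j, i] = False

    degree = pd.Series(retained.sum(axis=1).astype(int), index=ids, name="degree")
    return MINetwork(ids, mi, significant, retained, threshold, degree)


def compare_connectivity(network: MINetwork,
                         gene_groups: dict[str, list[str]],
                         reference_group: str) -> "ConnectivityComparison":
    """Kruskal-Wallis over group degree distributions, then pairwise
    two-sided Wilcoxon of each group against the reference, BH-corrected."""
    if reference_group not in gene_groups:
        raise ValueError(f"reference group {reference_group!r} missing")
    degrees = {}
    flagged = []
    for name, genes in gene_groups.items():
        present = [g for g in genes if g in network.degree.index]
        if len(present) < len(genes):
            logger.info("compare_connectivity: %d genes of %s not in network",
                        len(genes) - len(present), name)
        if len(present) < 3:
            flagged.append(name)
        degrees[name] = network.degree.loc[present].to_numpy(dtype=float)
    kw_stat, kw_p = stats.kruskal(*degrees.values())
    rows = []
    ref = degrees[reference_group]
    for name, d in degrees.items():
        if name == reference_group:
            continue
        stat, p = stats.mannwhitneyu(d, ref, alternative="two-sided",
                                     method="asymptotic")
        rows.append({"group": name, "n_genes": len(d),
                     "median_degree": float(np.median(d)) if len(d) else np.nan,
                     "statistic": float(stat), "p": float(p),
                     "flagged_small": name in flagged})
    pw = pd.DataFrame(rows)
    pw["q"] = bh_qvalues(pw["p"].to_numpy())
    return ConnectivityComparison(float(kw_stat), float(kw_p), pw,
                                  reference_group, flagged)


@dataclass
class ConnectivityComparison:
    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame
    reference: str
    flagged_small_groups: list[str]
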