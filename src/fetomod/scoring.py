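"""Sample-level ssGSEA scores, cell-level bin-matched module scores, and
nonparametric group comparisons of those scores.

ssGSEA follows the rank-weighted running-sum definition: within each
sample, genes are ranked by expression (average ranks for ties) and the
enrichment score is the summed difference between the weighted in-set
cumulative distribution (weight ``rank ** tau``) and the uniform out-of-set
cumulative distribution.  Being rank-based, scores are invariant to any
strictly monotone transform of a sample's expression values.

The cell-level score is the expression-bin-matched difference familiar
from single-cell module scoring: mean expression of the set genes minus
mean expression of control genes drawn from the same average-expression
bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection
from .multiple_testing import bh_qvalues

logger = logging.getLogger(__name__)


@dataclass
class SampleScoreTable:
    scores: pd.DataFrame      # rows = samples/cells, columns = gene sets
    method: str
    params: dict


def ssgsea(expr: ExpressionMatrix, gene_sets: GeneSetCollection,
           tau: float = 0.25, normalize: bool = True) -> SampleScoreTable:
    """Single-sample gene-set enrichment scores for every sample x set."""
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    n = expr.n_genes
    trimmed: dict[str, np.ndarray] = {}
    for name in gene_sets.names():
        members = [g for g in gene_sets[name] if g in gene_index]
        lost = len(gene_sets[name]) - len(members)
        if lost:
            logger.info("ssgsea: set %s trimmed by %d absent genes", name, lost)
        if not members:
            logger.warning("ssgsea: set %s has no genes in the matrix, skipped", name)
            continue
        if len(members) >= n:
            raise ValueError(f"gene set {name!r} covers every gene; "
                             "out-of-set walk undefined")
        mask = np.zeros(n, dtype=bool)
        mask[[gene_index[g] for g in members]] = True
        trimmed[name] = mask

    out = np.empty((expr.n_samples, len(trimmed)))
    set_names = list(trimmed)
    for s in range(expr.n_samples):
        x = expr.values[:, s]
        # average ranks for ties, largest expression -> largest rank value
        z = stats.rankdata(x, method="average")
        order = np.argsort(-x, kind="stable")
        for c, name in enumerate(set_names):
            out[s, c] = _es_walk(z, order, trimmed[name], tau)
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    frame = pd.DataFrame(out, index=expr.sample_ids, columns=set_names)
    return SampleScoreTable(frame, "ssgsea",
                            {"tau": tau, "normalize": normalize})


def _es_walk(z: np.ndarray, order: np.ndarray, in_set: np.ndarray,
             tau: float) -> float:
    zw = z[order] ** tau
    members = in_set[order]
    denom_in = zw[members].sum()
    denom_out = (~members).sum()
    step_in = np.where(members, zw / denom_in, 0.0)
    step_out = np.where(members, 0.0, 1.0 / denom_out)
    return float(np.cumsum(step_in - step_out).sum())


def cell_module_score(expr: ExpressionMatrix, gene_set: list[str],
                      nbin: int = 24, nctrl: int = 100,
                      seed: int = 0,
                      control_pool: list[str] | None = None) -> SampleScoreTable:
    """Bin-matched module score per cell (columns of ``expr`` are cells).

    Genes are split into ``nbin`` equal-count bins of mean expression; each
    set gene contributes ``nctrl`` control genes from its bin (without
    replacement when the bin is large enough).  The score is the per-cell
    mean of set genes minus the mean of the pooled controls.  Passing
    ``control_pool`` overrides sampling (used to verify the zero-score
    identity when controls equal the set itself).
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    members = [g for g in gene_set if g in gene_index]
    lost = len(gene_set) - len(members)
    if lost:
        logger.info("cell_module_score: %d set genes absent, dropped", lost)
    if not members:
        raise ValueError("no set genes present in the matrix")
    rows = [gene_index[g] for g in members]

    if control_pool is not None:
        ctrl_rows = [gene_index[g] for g in control_pool]
    else:
        mean_expr = expr.values.mean(axis=1)
        ranks = stats.rankdata(mean_expr, method="average")
        bins = np.minimum((ranks - 1) // np.ceil(len(ranks) / nbin), nbin - 1).astype(int)
        rng = np.random.default_rng(seed)
        ctrl_rows = []
        for r in rows:
            pool = np.flatnonzero(bins == bins[r])
            replace = len(pool) < nctrl
            ctrl_rows.extend(rng.choice(pool, size=nctrl, replace=replace))
    score = expr.values[rows].mean(axis=0) - expr.values[ctrl_rows].mean(axis=0)
    frame = pd.DataFrame({"module_score": score}, index=expr.sample_ids)
    return SampleScoreTable(frame, "cell_module_score",
                            {"nbin": nbin, "nctrl": nctrl, "seed": seed})


@dataclass
class GroupComparison:
    overall_test: str                  # "wilcoxon" or "kruskal-wallis"
    overall_stat: float
    overall_p: float
    pairwise: pd.DataFrame | None      # group, statistic, p, q (vs reference)


def compare_score_groups(scores: np.ndarray, labels: np.ndarray,
                         reference: str | None = None) -> GroupComparison:
    """Two groups: two-sided Wilcoxon rank-sum (normal approximation with
    tie correction).  More: Kruskal-Wallis, then pairwise Wilcoxon of each
    group against the reference group with BH correction."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: scores[labels == g] for g in groups}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if len(groups) == 2:
        stat, p = stats.mannwhitneyu(by_group[groups[0]], by_group[groups[1]],
                                     alternative="two-sided", method="asymptotic")
        return GroupComparison("wilcoxon", float(stat), float(p), None)
    kw_stat, kw_p = stats.kruskal(*by_group.values())
    if reference is None:
        reference = groups[0]
    if reference not in by_group:
        raise ValueError(f"reference group {reference!r} not present")
    rows = []
    for g in groups:
        if g == reference:
            continue
        stat, p = stats.mannwhitneyu(by_group[g], by_group[reference],
                                     alternative="two-sided", method="asymptotic")
        rows.append({"group": g, "statistic": float(stat), "p": float(p)})
    pw = pd.DataFrame(rows)
    pw["q"] = bh_qvalues(pw["p"].to_numpy())
    return GroupComparison("kruskal-wallis", float(kw_stat), float(kw_p), pw)
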