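"""Signed weighted co-expression network construction and module detection.

Pipeline: expression filter -> biweight midcorrelation -> signed
soft-thresholded adjacency -> topological overlap -> average-linkage
clustering with a top-down cut -> module eigengenes -> eigengene-correlation
merging.  Genes not assigned to any module carry the reserved ``grey``
label.

The network is built in a single block: at desk scale (a few thousand
genes) the full gene-gene matrix fits comfortably in memory, so the
block-wise decomposition used for genome-wide inputs is unnecessary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"


@dataclass
class NetworkParams:
    soft_power: int = 14
    signed: bool = True
    min_module_size: int = 30
    merge_cor_threshold: float = 0.85
    scale_free_target_r2: float = 0.8
    expressed_fraction: float = 0.9
    cut_height_frac: float = 0.99
    gap_frac: float = 0.25
    outlier_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        for name in ("merge_cor_threshold", "scale_free_target_r2",
                     "expressed_fraction", "cut_height_frac", "gap_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class TOMMatrix:
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("TOM entries must lie in [0, 1]")


@dataclass
class ModulePartition:
    """gene -> module label; ``grey`` marks unassigned genes."""

    labels: dict[str, str]

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == label]

    def modules(self) -> list[str]:
        return sorted({m for m in self.labels.values() if m != GREY})

    def n_assigned(self) -> int:
        return sum(1 for m in self.labels.values() if m != GREY)


@dataclass
class EigengeneMatrix:
    sample_ids: list[str]
    eigengenes: dict[str, np.ndarray]       # module -> per-sample values
    var_explained: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering / outliers
# ---------------------------------------------------------------------------

def filter_genes(expr: ExpressionMatrix,
                 expressed_fraction: float = 0.9) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in strictly more than
    ``expressed_fraction`` of samples, then drop zero-variance genes."""
    frac = (expr.values > 0).mean(axis=1)
    keep = frac > expressed_fraction
    keep &= expr.values.var(axis=1) > 0
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_genes: dropped %d of %d genes", n_drop, expr.n_genes)
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), expr.values[keep])


def detect_sample_outliers(expr: ExpressionMatrix,
                           cut_sd: float = 2.5) -> list[str]:
    """Flag samples whose first merge in an average-linkage tree on
    Euclidean sample distances happens unusually high
    (> mean + ``cut_sd`` * sd of all merge heights)."""
    if expr.n_samples < 4:
        raise ValueError("need at least 4 samples for outlier detection")
    z = linkage(expr.values.T, method="average", metric="euclidean")
    heights = z[:, 2]
    cut = heights.mean() + cut_sd * heights.std(ddof=0)
    first_merge = _leaf_first_merge_heights(z, expr.n_samples)
    return [s for s, h in zip(expr.sample_ids, first_merge) if h > cut]


def _leaf_first_merge_heights(z: np.ndarray, n: int) -> np.ndarray:
    heights = np.full(2 * n - 1, np.nan)
    for a, b, h, _ in z:
        for child in (int(a), int(b)):
            if np.isnan(heights[child]):
                heights[child] = h
    return heights[:n]


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight transform of one vector; Pearson fallback at MAD=0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - x.mean()
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors.

    If either vector has zero MAD the pair falls back to Pearson (a robust
    location/scale cannot be formed for it).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("bicor needs two equal-length vectors, n >= 3")
    if (np.median(np.abs(x - np.median(x))) == 0
            or np.median(np.abs(y - np.median(y))) == 0):
        xt, yt = x - x.mean(), y - y.mean()
    else:
        xt = _bicor_transform(x)
        yt = _bicor_transform(y)
    nx, ny = np.linalg.norm(xt), np.linalg.norm(yt)
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip(xt @ yt / (nx * ny), -1.0, 1.0))


def bicor_matrix(values: np.ndarray) -> np.ndarray:
    """Row-by-row biweight midcorrelation of a genes x samples matrix."""
    t = np.empty_like(values, dtype=float)
    for i in range(values.shape[0]):
        t[i] = _bicor_transform(values[i])
    norms = np.linalg.norm(t, axis=1)
    norms[norms == 0] = np.nan
    c = (t @ t.T) / np.outer(norms, norms)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: ExpressionMatrix, params: NetworkParams,
              cor: np.ndarray | None = None) -> np.ndarray:
    """Soft-thresholded adjacency; signed: ``((1 + cor)/2) ** beta``."""
    c = bicor_matrix(expr.values) if cor is None else cor
    if params.signed:
        a = ((1.0 + c) / 2.0) ** params.soft_power
    else:
        a = np.abs(c) ** params.soft_power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(expr: ExpressionMatrix,
                        candidate_powers: list[int] | None = None,
                        target_r2: float = 0.8,
                        signed: bool = True) -> tuple[int, "np.ndarray"]:
    """Smallest candidate power reaching approximate scale-free topology.

    For each power the connectivity distribution is binned into 10
    equal-count bins and log10(frequency) regressed on log10(mean k); the
    fit index is R^2 times the negated slope sign, so only a decreasing
    power-law counts as scale-free.  Returns (power, fit table with columns
    power / signed_r2 / mean_k).
    """
    import pandas as pd

    if expr.n_genes < 50:
        raise ValueError("need >= 50 genes to assess scale-free fit")
    powers = candidate_powers or [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20]
    c = bicor_matrix(expr.values)
    rows = []
    chosen = None
    for beta in powers:
        a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2 = _scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "mean_k": float(k.mean())})
        if chosen is None and r2 >= target_r2:
            chosen = beta
    table = pd.DataFrame(rows)
    if chosen is None:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return chosen, table


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    k = k[k > 0]
    if len(k) < n_bins:
        return -1.0
    qs = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    idx = np.clip(np.searchsorted(qs, k, side="right") - 1, 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan
                       for b in range(n_bins)])
    freq = np.array([(idx == b).mean() for b in range(n_bins)])
    ok = np.isfinite(mean_k) & (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return -1.0
    x = np.log10(mean_k[ok])
    y = np.log10(freq[ok])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * -np.sign(slope))


# ---------------------------------------------------------------------------
# topological overlap and tree cutting
# ---------------------------------------------------------------------------

def tom(adj: np.ndarray, gene_ids: list[str] | None = None) -> TOMMatrix:
    """Topological overlap: shared-neighbour-augmented adjacency.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``.
    """
    a = np.array(adj, dtype=float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # includes u = i or j terms only through zeroed diagonal
    num = L + a
    kmin = np.minimum.outer(k, k)
    t = num / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    ids = gene_ids if gene_ids is not None else [str(i) for i in range(len(a))]
    return TOMMatrix(ids, t)


def cut_modules(tom_matrix: TOMMatrix, params: NetworkParams) -> ModulePartition:
    """Top-down cut of the average-linkage tree on 1 - TOM.

    A static cut at ``cut_height_frac`` of the merge-height *range*
    (``h_min + frac * (h_max - h_min)``; TOM dissimilarities compress near 1,
    so a fraction of the absolute maximum is not scale-free) yields coarse
    clusters.  Clusters of at least ``min_module_size`` genes whose mean
    internal topological overlap clearly exceeds the matrix-wide background
    become modules; this guard sends the loose clump that pure-noise data
    forms below any cut to grey.  One refinement pass re-cuts any module
    whose internal merge heights show a gap larger than ``gap_frac`` of
    their range (two factors fused into one branch), keeping sub-clusters
    of sufficient size.  Everything else is grey.
    """
    genes = tom_matrix.gene_ids
    d = 1.0 - tom_matrix.values
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    h0 = heights.min() + params.cut_height_frac * (heights.max() - heights.min())
    coarse = fcluster(z, t=h0, criterion="distance")

    t_off = tom_matrix.values.copy()
    np.fill_diagonal(t_off, 0.0)
    n = len(genes)

    labels = {g: GREY for g in genes}
    module_members: list[list[int]] = []
    for c in np.unique(coarse):
        members = np.flatnonzero(coarse == c)
        if len(members) < params.min_module_size:
            continue
        m = len(members)
        within = t_off[np.ix_(members, members)].sum() / (m * (m - 1))
        outside = np.setdiff1d(np.arange(n), members, assume_unique=True)
        if outside.size:
            between = t_off[np.ix_(members, outside)].mean()
        else:  # cluster swallowed every gene: no contrast available
            between = within
        if within < 2.0 * max(between, 1e-300):
            # a real module is denser inside than toward the rest of the
            # network; the loose clump pure noise forms is not
            logger.info("cut_modules: cluster of %d genes rejected "
                        "(within %.2g vs between %.2g)", m, within, between)
            continue
        module_members.extend(_refine_cluster(members, d, params))
    # deterministic naming: size-descending, ties by first gene id
    module_members.sort(key=lambda m: (-len(m), genes[min(m)]))
    for rank, members in enumerate(module_members, 1):
        for i in members:
            labels[genes[i]] = f"M{rank:02d}"
    return ModulePartition(labels)


def _refine_cluster(members: np.ndarray, d: np.ndarray,
                    params: NetworkParams) -> list[list[int]]:
    if len(members) < 2 * params.min_module_size:
        return [list(members)]
    sub = d[np.ix_(members, members)]
    z = linkage(squareform(sub, checks=False), method="average")
    heights = np.sort(z[:, 2])
    span = heights[-1] - heights[0]
    if span <= 0:
        return [list(members)]
    gaps = np.diff(heights)
    g = int(np.argmax(gaps))
    if gaps[g] <= params.gap_frac * span:
        return [list(members)]
    cut = (heights[g] + heights[g + 1]) / 2.0
    assign = fcluster(z, t=cut, criterion="distance")
    parts = [members[np.flatnonzero(assign == c)] for c in np.unique(assign)]
    kept = [list(p) for p in parts if len(p) >= params.min_module_size]
    if len(kept) < 2:  # the gap did not separate real sub-modules
        return [list(members)]
    return kept


# ---------------------------------------------------------------------------
# eigengenes and merging
# ---------------------------------------------------------------------------

def eigengene(expr: ExpressionMatrix, partition: ModulePartition) -> EigengeneMatrix:
    """Per-module first principal component of the standardized submatrix,
    unit variance, oriented to correlate positively with the module's mean
    expression profile."""
    eg: dict[str, np.ndarray] = {}
    ve: dict[str, float] = {}
    for module in partition.modules():
        genes = partition.module_genes(module)
        if len(genes) < 2:
            raise ValueError(f"module {module!r} has < 2 genes")
        sub = expr.subset_genes(genes).values
        z = sub - sub.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z /= sd[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        if np.corrcoef(pc1, sub.mean(axis=0))[0, 1] < 0:
            pc1 = -pc1
        eg[module] = (pc1 - pc1.mean()) / pc1.std(ddof=0)
        ve[module] = float(s[0] ** 2 / (s ** 2).sum())
    return EigengeneMatrix(list(expr.sample_ids), eg, ve)


def merge_modules(expr: ExpressionMatrix, partition: ModulePartition,
                  threshold: float = 0.85) -> ModulePartition:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds ``threshold``, recomputing eigengenes
    after every merge.  Ties break lexicographically; the merged module
    keeps the larger member's name (lexicographic on equal size)."""
    labels = dict(partition.labels)
    while True:
        part = ModulePartition(labels)
        modules = part.modules()
        if len(modules) < 2:
            break
        em = eigengene(expr, part)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                r = float(np.corrcoef(em.eigengenes[a], em.eigengenes[b])[0, 1])
                if best is None or r > best[0] + 1e-15:
                    best = (r, a, b)
        assert best is not None
        r, a, b = best
        if r <= threshold:
            break
        size_a, size_b = len(part.module_genes(a)), len(part.module_genes(b))
        if size_a == size_b:
            keep, drop = min(a, b), max(a, b)
        elif size_a > size_b:
            keep, drop = a, b
        else:
            keep, drop = b, a
        logger.info("merge_modules: merging %s into %s (r=%.3f)", drop, keep, r)
        for g, m in labels.items():
            if m == drop:
                labels[g] = keep
    return ModulePartition(labels)


def run_network(expr: ExpressionMatrix, params: NetworkParams | None = None
                ) -> tuple[ExpressionMatrix, TOMMatrix, ModulePartition, EigengeneMatrix]:
    """Filter -> adjacency -> TOM -> cut -> merge -> eigengenes."""
    params = params or NetworkParams()
    filtered = filter_genes(expr, params.expressed_fraction)
    adj = adjacency(filtered, params)
    t = tom(adj, list(filtered.gene_ids))
    part = cut_modules(t, params)
    if part.modules():
        part = merge_modules(filtered, part, params.merge_cor_threshold)
        em = eigengene(filtered, part)
    else:
        em = EigengeneMatrix(list(filtered.sample_ids), {}, {})
    return filtered, t, part, em
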