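"""Benjamini-Hochberg step-up false discovery rate control."""

from __future__ import annotations

import numpy as np


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Step-up adjusted p-values: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_threshold(pvalues: np.ndarray, level: float = 0.05) -> float | None:
    """Largest raw p-value rejected by BH at ``level`` (None if no rejection)."""
    q = bh_qvalues(pvalues)
    rejected = np.asarray(pvalues, float)[q <= level]
    return float(rejected.max()) if rejected.size else None
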