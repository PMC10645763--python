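"""Two-sample Mendelian randomization estimators and sensitivity analyses.

Exposure effects come from per-SNP eQTL-style summary statistics (here,
effects on module activity), outcome effects from an independent GWAS.
After allele harmonization the package provides the fixed-effects
inverse-variance-weighted estimator, the weighted median (consistent when
at least half the instrument weight is valid), MR-Egger slope plus its
intercept test for directional pleiotropy, Cochran's Q heterogeneity,
leave-one-out and single-SNP Wald analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EQTLRecord, GWASSummaryRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizedInstruments:
    """Per-SNP exposure/outcome effect pairs on a shared effect allele."""

    table: pd.DataFrame  # snp, beta_exp, se_exp, beta_out, se_out, flipped
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0

    def __post_init__(self) -> None:
        if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "HarmonizedInstruments":
        return HarmonizedInstruments(self.table[mask].reset_index(drop=True))


@dataclass
class MREstimate:
    method: str
    estimate: float
    se: float
    p: float
    n_snps: int
    flags: list[str] = field(default_factory=list)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.959963984540054 * self.se,
                self.estimate + 1.959963984540054 * self.se)


@dataclass
class SensitivityReport:
    cochran_q: float
    df: int
    q_p: float
    leave_one_out: pd.DataFrame    # excluded snp, estimate, se, p
    single_snp: pd.DataFrame       # snp, wald ratio, se, p
    egger_intercept: MREstimate | None = None


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(exposure: Sequence[EQTLRecord],
              outcome: Sequence[GWASSummaryRecord]) -> HarmonizedInstruments:
    """Align outcome effects to the exposure effect allele.

    Palindromic (A/T, C/G) SNPs are dropped unconditionally — their strand
    cannot be resolved from alleles alone.  Swapped alleles (directly or on
    the complementary strand) negate the outcome beta; any other allele
    combination drops the SNP.
    """
    out_by_id = {r.snp.snp_id: r for r in outcome}
    rows = []
    n_palindromic = n_unmatched = 0
    for exp in exposure:
        out = out_by_id.get(exp.snp.snp_id)
        if out is None:
            continue
        if exp.snp.is_palindromic or out.snp.is_palindromic:
            n_palindromic += 1
            continue
        e_pair = (exp.snp.effect_allele, exp.snp.other_allele)
        o_pair = (out.snp.effect_allele, out.snp.other_allele)
        o_comp = (_COMPLEMENT[o_pair[0]], _COMPLEMENT[o_pair[1]])
        if o_pair == e_pair or o_comp == e_pair:
            beta_out, flipped = out.beta, False
        elif o_pair == e_pair[::-1] or o_comp == e_pair[::-1]:
            beta_out, flipped = -out.beta, True
        else:
            n_unmatched += 1
            logger.info("harmonize: allele mismatch for %s, dropped", exp.snp.snp_id)
            continue
        rows.append({"snp": exp.snp.snp_id, "beta_exp": exp.beta,
                     "se_exp": exp.se, "beta_out": beta_out,
                     "se_out": out.se, "flipped": flipped})
    if not rows:
        raise ValueError("no SNPs remain after harmonization")
    if n_palindromic:
        logger.info("harmonize: dropped %d palindromic SNPs", n_palindromic)
    return HarmonizedInstruments(pd.DataFrame(rows), n_palindromic, n_unmatched)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def mr_ivw(h: HarmonizedInstruments,
           random_effects: bool = False) -> MREstimate:
    """Fixed-effects IVW: weighted regression of beta_out on beta_exp
    through the origin with weights 1/se_out^2.

    With a single SNP the Wald ratio is returned instead, flagged.  The
    non-default multiplicative random-effects variant inflates the standard
    error by sqrt(Q / (n - 1)) when heterogeneity exceeds its expectation.
    """
    t = h.table
    if len(t) < 2:
        r = t["beta_out"].iloc[0] / t["beta_exp"].iloc[0]
        se = t["se_out"].iloc[0] / abs(t["beta_exp"].iloc[0])
        p = 2 * stats.norm.sf(abs(r / se))
        return MREstimate("wald", float(r), float(se), float(p), 1,
                          flags=["single_snp"])
    w = 1.0 / t["se_out"] ** 2
    sxx = float((w * t["beta_exp"] ** 2).sum())
    estimate = float((w * t["beta_exp"] * t["beta_out"]).sum()) / sxx
    se = 1.0 / np.sqrt(sxx)
    flags = []
    if random_effects:
        q = cochran_q(h, estimate)
        scale = max(1.0, q / (len(t) - 1))
        se *= np.sqrt(scale)
        flags.append("multiplicative_random_effects")
    p = 2 * stats.norm.sf(abs(estimate / se))
    return MREstimate("ivw", estimate, float(se), float(p), len(t), flags)


def mr_weighted_median(h: HarmonizedInstruments, n_boot: int = 1000,
                       seed: int = 0) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Weights ``(beta_exp / se_out)^2`` are normalized; the estimate is the
    linear interpolation where the half-step-offset cumulative weight
    crosses 0.5.  The standard error comes from a parametric bootstrap of
    the summary statistics.
    """
    t = h.table
    keep = t["beta_exp"] != 0
    if (~keep).any():
        logger.info("mr_weighted_median: dropped %d SNPs with beta_exp = 0",
                    int((~keep).sum()))
        t = t[keep]
    if len(t) < 3:
        raise ValueError("weighted median needs >= 3 SNPs")
    est = _weighted_median_estimate(t["beta_exp"].to_numpy(),
                                    t["beta_out"].to_numpy(),
                                    t["se_out"].to_numpy())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    be = t["beta_exp"].to_numpy()
    bo = t["beta_out"].to_numpy()
    se_e = t["se_exp"].to_numpy()
    se_o = t["se_out"].to_numpy()
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, se_o)
        ok = be_b != 0
        boots[b] = _weighted_median_estimate(be_b[ok], bo_b[ok], se_o[ok])
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se))
    return MREstimate("weighted_median", float(est), se, float(p), len(t))


def _weighted_median_estimate(beta_exp: np.ndarray, beta_out: np.ndarray,
                              se_out: np.ndarray) -> float:
    ratios = beta_out / beta_exp
    weights = (beta_exp / se_out) ** 2
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, r))


def mr_egger(h: HarmonizedInstruments) -> tuple[MREstimate, MREstimate]:
    """Weighted regression of beta_out on beta_exp *with* an intercept.

    Exposure orientation is forced non-negative first (flipping the sign of
    both members of a pair leaves the causal effect unchanged).  The
    intercept estimate is the directional-pleiotropy test; inference uses a
    t reference with n - 2 degrees of freedom.
    """
    t = h.table
    if len(t) < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    sign = np.where(t["beta_exp"] < 0, -1.0, 1.0)
    x = t["beta_exp"].to_numpy() * sign
    y = t["beta_out"].to_numpy() * sign
    w = 1.0 / t["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx_inv = np.linalg.inv(X.T @ WX)
    coef = xtwx_inv @ (WX.T @ y)
    resid = y - X @ coef
    df = len(t) - 2
    sigma2 = float((w * resid ** 2).sum()) / df
    cov = xtwx_inv * sigma2
    ses = np.sqrt(np.diag(cov))
    ps = 2 * stats.t.sf(np.abs(coef / ses), df=df)
    slope = MREstimate("egger_slope", float(coef[1]), float(ses[1]),
                       float(ps[1]), len(t))
    intercept = MREstimate("egger_intercept", float(coef[0]), float(ses[0]),
                           float(ps[0]), len(t))
    return slope, intercept


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

def cochran_q(h: HarmonizedInstruments, ivw_estimate: float) -> float:
    t = h.table
    w = 1.0 / t["se_out"] ** 2
    return float((w * (t["beta_out"] - ivw_estimate * t["beta_exp"]) ** 2).sum())


def sensitivity(h: HarmonizedInstruments,
                ivw_estimate: MREstimate | None = None,
                include_egger: bool = True) -> SensitivityReport:
    """Cochran's Q, leave-one-out IVW, single-SNP Wald ratios, Egger intercept."""
    if ivw_estimate is None:
        ivw_estimate = mr_ivw(h)
    t = h.table
    n = len(t)
    q = cochran_q(h, ivw_estimate.estimate)
    df = n - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")

    loo_rows = []
    if n > 2:
        for i in range(n):
            sub = h.subset(np.arange(n) != i)
            est = mr_ivw(sub)
            loo_rows.append({"excluded_snp": t["snp"].iloc[i],
                             "estimate": est.estimate, "se": est.se, "p": est.p})
    loo = pd.DataFrame(loo_rows)

    ratios = t["beta_out"] / t["beta_exp"]
    wald_se = t["se_out"] / t["beta_exp"].abs()
    single = pd.DataFrame({
        "snp": t["snp"],
        "wald_ratio": ratios,
        "se": wald_se,
        "p": 2 * stats.norm.sf((ratios / wald_se).abs()),
    }).reset_index(drop=True)

    egger_int = None
    if include_egger and n >= 3:
        _, egger_int = mr_egger(h)
    return SensitivityReport(q, df, q_p, loo, single, egger_int)
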