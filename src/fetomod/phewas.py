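"""Phenome-wide scan of one polygenic score against many outcomes.

Each outcome is typed automatically (binary / ordinal / continuous), fitted
with the matching regression family under complete-case covariate
adjustment, and the batch is corrected with Benjamini-Hochberg FDR.  The
plot-ready summary carries the signed -log10 p convention used in Miami
plots: the direction of effect multiplies the log p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .multiple_testing import bh_qvalues, bh_threshold

logger = logging.getLogger(__name__)

FAMILIES = ("continuous", "binary", "ordinal")


def classify_outcome(values: pd.Series | np.ndarray,
                     min_nonmissing: int = 50,
                     max_ordinal_levels: int = 20) -> str | None:
    """binary (2 levels) / ordinal (integers, <= 20 levels) / continuous.

    Returns None (with a log message) for outcomes with a single distinct
    value; raises if too few non-missing observations.
    """
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if len(v) < min_nonmissing:
        raise ValueError(f"only {len(v)} non-missing values (< {min_nonmissing})")
    distinct = np.unique(v)
    if len(distinct) == 1:
        logger.info("classify_outcome: constant outcome skipped")
        return None
    if len(distinct) == 2:
        return "binary"
    if np.allclose(distinct, np.round(distinct)) and len(distinct) <= max_ordinal_levels:
        return "ordinal"
    return "continuous"


@dataclass
class PheWASResult:
    table: pd.DataFrame   # outcome, family, beta, se, p, q, n, signed_mlog10p
    fdr_level: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.fdr_level]


def _expand_covariates(covariates: pd.DataFrame | None,
                       index: pd.Index) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=index)
    cov = covariates.loc[index].copy()
    pieces = []
    for col in cov.columns:
        s = cov[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            ref = s.mode().iloc[0]  # most frequent level is the reference
            dummies = pd.get_dummies(s, prefix=col, dtype=float)
            dummies = dummies.drop(columns=f"{col}_{ref}")
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float))
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=index)


def run_phewas(pgs: pd.Series, outcomes: pd.DataFrame,
               covariates: pd.DataFrame | None = None,
               fdr_level: float = 0.05,
               min_nonmissing: int = 50,
               categories: dict[str, str] | None = None) -> PheWASResult:
    """Fit PGS -> outcome regressions outcome by outcome, BH-correct.

    Outcomes that are constant, fail to converge, or show separation are
    excluded from the FDR batch with a log message and reported with
    ``family = 'failed'``.
    """
    rows = []
    for name in outcomes.columns:
        y_all = outcomes[name]
        keep = y_all.notna() & pgs.notna()
        if covariates is not None:
            keep &= covariates.notna().all(axis=1)
        idx = outcomes.index[keep]
        try:
            family = classify_outcome(y_all[idx], min_nonmissing)
        except ValueError as exc:
            logger.warning("phewas: outcome %s skipped (%s)", name, exc)
            continue
        if family is None:
            continue
        X = _expand_covariates(covariates, idx)
        X.insert(0, "pgs", pgs.loc[idx].astype(float))
        y = y_all.loc[idx].astype(float)
        try:
            beta, se, p = _fit_family(y, X, family)
        except Exception as exc:  # non-convergence / separation
            logger.warning("phewas: outcome %s failed to fit (%s)", name, exc)
            rows.append({"outcome": name, "family": "failed", "beta": np.nan,
                         "se": np.nan, "p": np.nan, "n": int(keep.sum())})
            continue
        rows.append({"outcome": name, "family": family, "beta": beta,
                     "se": se, "p": p, "n": int(keep.sum())})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no outcome could be fitted")
    fitted = table["family"] != "failed"
    q = np.full(len(table), np.nan)
    q[fitted.to_numpy()] = bh_qvalues(table.loc[fitted, "p"].to_numpy())
    table["q"] = q
    with np.errstate(divide="ignore"):
        table["signed_mlog10p"] = -np.log10(table["p"]) * np.sign(table["beta"])
    if categories:
        table["category"] = table["outcome"].map(categories).fillna("other")
    return PheWASResult(table, fdr_level)


def _fit_family(y: pd.Series, X: pd.DataFrame, family: str
                ) -> tuple[float, float, float]:
    X = X.astype(float)
    if family == "continuous":
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        return float(fit.params["pgs"]), float(fit.bse["pgs"]), float(fit.pvalues["pgs"])
    if family == "binary":
        yb = (y == y.max()).astype(float)
        fit = sm.Logit(yb, sm.add_constant(X)).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge")
        if np.abs(fit.params).max() > 30:
            raise RuntimeError("separation suspected in logistic fit")
        return float(fit.params["pgs"]), float(fit.bse["pgs"]), float(fit.pvalues["pgs"])
    if family == "ordinal":
        model = OrderedModel(y, X, distr="logit")
        fit = model.fit(method="bfgs", disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("proportional-odds fit did not converge")
        return float(fit.params["pgs"]), float(fit.bse["pgs"]), float(fit.pvalues["pgs"])
    raise ValueError(f"unknown family {family!r}")


def miami_table(result: PheWASResult) -> tuple[pd.DataFrame, float | None]:
    """Signed -log10 p per outcome plus the BH threshold line (the largest
    raw p passing FDR; None when nothing is significant)."""
    fitted = result.table[result.table["family"] != "failed"].copy()
    threshold = bh_threshold(fitted["p"].to_numpy(), result.fdr_level)
    cols = ["outcome", "family", "beta", "p", "q", "signed_mlog10p"]
    if "category" in fitted.columns:
        cols.append("category")
    return fitted[cols], threshold
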