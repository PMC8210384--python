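"""Descriptive trend layer: weighted rates, chi-square tests, logistic ORs.

These are the standard survey-analysis companions to the inequity
measures: weighted utilization rates per group and wave, Pearson
chi-square tests of rate differences across waves, and a pooled
multivariable logistic regression reporting adjusted odds ratios with Wald
confidence limits (reference levels carry OR = 1 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import fit_binary_model

__all__ = [
    "ChiSquareResult",
    "utilization_rate",
    "rate_table",
    "chi_square_test",
    "fit_logistic_or",
]


def utilization_rate(y, weights=None) -> float:
    """Weighted mean of a binary outcome."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty outcome vector")
    if weights is None:
        return float(y.mean())
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return float((w @ y) / w.sum())


def rate_table(cohort: pd.DataFrame, outcome: str, by, weight_var=None) -> pd.DataFrame:
    """Weighted outcome rate per group, with group size."""
    rows = []
    for key, g in cohort.groupby(by, observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        w = None if weight_var is None else g[weight_var].to_numpy()
        rows.append(
            dict(zip(by if isinstance(by, list) else [by], key))
            | {"rate": utilization_rate(g[outcome].to_numpy(), w), "n": len(g)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table, correction: str = "none") -> ChiSquareResult:
    """Pearson chi-square test of independence on an r×c count table.

    ``correction="yates"`` applies the continuity correction (2×2 tables);
    the default is the uncorrected large-sample statistic. Degenerate
    tables (a zero row or column margin) are rejected.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("table must be a 2-d nonnegative count matrix")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column marginal")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction: {correction!r}")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=(correction == "yates"))
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p))


def fit_logistic_or(X: pd.DataFrame, y, weights=None, level: float = 0.95,
                    reference_levels: dict | None = None) -> pd.DataFrame:
    """Multivariable logistic regression reported as odds ratios.

    Returns a frame with one row per design column: ``odds_ratio``,
    ``cl_lower``, ``cl_upper`` (Wald, ``exp(β ± z·SE)``) and a
    ``reference`` flag. ``reference_levels`` maps variable names to the
    label of their omitted level; each appears as an OR = 1 row ahead of
    its dummies, mirroring how adjusted-OR tables are printed.
    """
    fit = fit_binary_model(X, y, weights, link="logit")
    se = np.sqrt(np.diag(fit.covariance))
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    names = fit.names
    inserted = set()
    for i, name in enumerate(names):
        if name == "const":
            continue
        if reference_levels:
            for var, ref in reference_levels.items():
                if var not in inserted and name.startswith(var):
                    rows.append({"variable": var, "level": ref, "odds_ratio": 1.0,
                                 "cl_lower": np.nan, "cl_upper": np.nan,
                                 "reference": True})
                    inserted.add(var)
        b = fit.coefficients[name]
        rows.append({
            "variable": name,
            "level": "",
            "odds_ratio": float(np.exp(b)),
            "cl_lower": float(np.exp(b - z * se[i])),
            "cl_upper": float(np.exp(b + z * se[i])),
            "reference": False,
        })
    return pd.DataFrame(rows)
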