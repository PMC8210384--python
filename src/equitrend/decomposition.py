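"""Decomposition of the concentration index and the horizontal inequity index.

For a binary outcome the index is decomposed through a probit model used to
indirectly standardize utilization for need. With average marginal effects
:math:`\\beta^m_k` from the fitted probit, elasticities
:math:`\\eta_k = \\beta^m_k \\bar x_k / \\mu` and determinant concentration
indices :math:`C_k` (standard index of :math:`x_k` over the same income
ranks), the standard index satisfies approximately

.. math:: C = \\sum_k \\eta_k C_k + \\text{residual},

where the residual absorbs the generalized-error term and the linear
approximation error of the nonlinear model, and is computed here as the
exact closure term. The horizontal inequity index removes legitimate
need-driven inequality: ``HI = C − Σ(need contributions)``; the adjusted
form divides by the binary-outcome normalization factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .ranks import (
    DegenerateDataWarning,
    concentration_index,
    fractional_rank,
    generalized_concentration_index,
)

__all__ = [
    "ModelFit",
    "DecompositionRow",
    "DecompositionTable",
    "fit_binary_model",
    "average_marginal_effects",
    "elasticity",
    "percentage_contribution",
    "decompose",
    "horizontal_inequity",
    "adjust_horizontal_inequity",
]


@dataclass(frozen=True)
class ModelFit:
    """A fitted weighted binary-outcome regression (probit or logit)."""

    link: str
    coefficients: dict
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n: int

    @property
    def names(self) -> list:
        return list(self.coefficients)

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    vals = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(vals)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}): collinear columns"
        )
    uy = np.unique(y)
    if not np.all(np.isin(uy, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")


def _separation_check(X: pd.DataFrame, y: np.ndarray) -> None:
    # a binary column perfectly aligned with y guarantees ML divergence
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        u = np.unique(col)
        if u.size == 2:
            lo, hi = col == u[0], col == u[1]
            if (y[lo].max(initial=0) < y[hi].min(initial=1)) or (
                y[hi].max(initial=0) < y[lo].min(initial=1)
            ):
                raise ValueError(f"perfect separation on variable {name!r}")


def fit_binary_model(X: pd.DataFrame, y, weights=None, link: str = "probit") -> ModelFit:
    """Weighted maximum-likelihood probit/logit fit.

    ``X`` is the design matrix without a constant (one is added, named
    ``const``). Weights enter the pseudo-likelihood as variance weights;
    the coefficient covariance is the HC0 sandwich, appropriate for survey
    weights. Deterministic for fixed input.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    w = w * (len(w) / w.sum())  # normalize to mean 1: keeps n the effective size
    if X.shape[1] > 0:
        _check_design(X, y)
        _separation_check(X, y)
    Xc = sm.add_constant(X, has_constant="add")

    if link == "probit":
        fam = sm.families.Binomial(link=sm.families.links.Probit())
    elif link == "logit":
        fam = sm.families.Binomial(link=sm.families.links.Logit())
    else:
        raise ValueError(f"unknown link: {link!r}")

    model = sm.GLM(y, Xc, family=fam, var_weights=w)
    res = model.fit(maxiter=200, tol=1e-10, cov_type="HC0")
    converged = bool(res.converged)
    coefficients = dict(zip(Xc.columns, np.asarray(res.params, dtype=float)))
    return ModelFit(
        link=link,
        coefficients=coefficients,
        covariance=np.asarray(res.cov_params(), dtype=float),
        log_likelihood=float(res.llf),
        converged=converged,
        n=len(y),
    )


def average_marginal_effects(fit: ModelFit, X: pd.DataFrame, weights=None,
                             at_means: bool = False) -> dict:
    """Linear-approximation marginal effects for the decomposition.

    Every regressor (dummies included) is treated as continuous:
    ``β^m_k = E_w[f(x'β)]·β_k`` with ``f`` the link density (``φ`` for the
    probit), evaluated observation-by-observation and averaged with the
    sampling weights — or at the weighted covariate means when
    ``at_means`` is set. A single scale factor multiplies every
    coefficient, which is what lets the decomposition identity use one
    linear coefficient per variable.
    """
    if not fit.converged:
        raise ValueError("model did not converge; marginal effects refused")
    names = [n for n in fit.names if n != "const"]
    if not names:
        return {}
    Xc = sm.add_constant(X[names], has_constant="add")[fit.names]
    eta = Xc.to_numpy(dtype=float) @ fit.beta
    w = np.ones(len(eta)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    if fit.link == "probit":
        dens = norm.pdf
    else:
        dens = lambda t: np.exp(-t) / (1.0 + np.exp(-t)) ** 2
    if at_means:
        scale = float(dens(float((w @ Xc.to_numpy(dtype=float)) @ fit.beta)))
    else:
        scale = float(w @ dens(eta))
    return {n: scale * fit.coefficients[n] for n in names}


def elasticity(marginal_effect: float, mean_x: float, mu: float) -> float:
    """Elasticity of the outcome mean to determinant k: ``β^m_k·x̄_k/μ``."""
    if mu <= 0:
        raise ValueError("elasticity undefined: mean outcome must be positive")
    return marginal_effect * mean_x / mu


def percentage_contribution(contribution: float, total_index: float) -> float:
    """Percentage contribution: ``100·contribution/total_index``."""
    if total_index == 0:
        raise ValueError("percentage contribution undefined: total index is zero")
    return 100.0 * contribution / total_index


@dataclass(frozen=True)
class DecompositionRow:
    """One determinant's share of the income-related inequality."""

    variable: str
    role: str  # "need" or "non-need"
    mean_x: float
    marginal_effect: float
    elasticity: float
    determinant_ci: float
    contribution: float
    pct_contribution: float


@dataclass(frozen=True)
class DecompositionTable:
    """Full decomposition of the (standard-scale) concentration index.

    ``total_index`` is the standard concentration index C of the outcome;
    ``residual`` is the exact closure term ``C − Σ contributions``;
    ``hi = C − Σ(need contributions)``; ``hi_adjusted`` is HI on the
    binary-outcome normalized scale (identical whether computed from the
    standard-scale HI via ÷(1−μ) or from the covariance-scale HI via
    ÷μ(1−μ)).
    """

    rows: list
    total_index: float
    residual: float
    hi: float
    hi_adjusted: float
    mu: float
    n: int

    def to_frame(self, scale: str = "standard") -> pd.DataFrame:
        """Tabulate; ``scale="covariance"`` multiplies index-scale columns
        by μ, giving values comparable to covariance-scale reporting."""
        f = self.mu if scale == "covariance" else 1.0
        df = pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "role": r.role,
                    "mean_x": r.mean_x,
                    "marginal_effect": r.marginal_effect,
                    "elasticity": r.elasticity,
                    "determinant_ci": r.determinant_ci,
                    "contribution": r.contribution * f,
                    "pct_contribution": r.pct_contribution,
                }
                for r in self.rows
            ]
        )
        return df

    @property
    def need_contribution(self) -> float:
        return sum(r.contribution for r in self.rows if r.role == "need")


def horizontal_inequity(total_index: float, table) -> float:
    """HI: total index minus the summed contributions of need variables.

    ``table`` may be a DecompositionTable or an iterable of need-row
    contributions. An empty need set returns the total index unchanged
    (with a warning when a table carries no need rows).
    """
    if isinstance(table, DecompositionTable):
        need = [r.contribution for r in table.rows if r.role == "need"]
        if not need:
            warnings.warn(
                "no rows marked 'need': horizontal inequity equals the total index",
                DegenerateDataWarning,
                stacklevel=2,
            )
        return total_index - sum(need)
    return total_index - float(np.sum(np.asarray(list(table), dtype=float)))


def adjust_horizontal_inequity(hi: float, mu: float) -> float:
    """Normalize a covariance-scale HI for a binary outcome: ``hi/(μ(1−μ))``."""
    if not 0.0 < mu < 1.0:
        raise ValueError("adjusted HI undefined: mu must lie strictly in (0, 1)")
    return hi / (mu * (1.0 - mu))


def decompose(
    cohort: pd.DataFrame,
    outcome: str,
    rank_var: str,
    determinants: dict,
    weight_var: str | None = None,
    link: str = "probit",
    at_means: bool = False,
) -> DecompositionTable:
    """Decompose the concentration index of a binary outcome.

    Parameters
    ----------
    cohort
        Long-format frame holding the outcome, ranking variable, weights
        and numeric determinant columns (dummies pre-coded).
    determinants
        Ordered map ``column -> role`` with role ``"need"`` or
        ``"non-need"``; table rows follow this order.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    w = (np.ones(len(y)) if weight_var is None
         else cohort[weight_var].to_numpy(dtype=float))
    wn = w / w.sum()
    gamma = fractional_rank(cohort[rank_var].to_numpy(dtype=float), w)
    mu = float(wn @ y)
    if not 0.0 < mu < 1.0:
        raise ValueError("decomposition undefined at degenerate prevalence")
    total = generalized_concentration_index(y, gamma, w) / mu

    X = cohort[list(determinants)].astype(float)
    fit = fit_binary_model(X, y, w, link=link)
    ame = average_marginal_effects(fit, X, w, at_means=at_means)

    rows = []
    for var, role in determinants.items():
        xk = X[var].to_numpy()
        mean_x = float(wn @ xk)
        if np.all(xk == xk[0]) or mean_x == 0.0:
            ck = 0.0
        else:
            ck = concentration_index(xk, gamma, w)
        eta = elasticity(ame[var], mean_x, mu)
        contrib = eta * ck
        rows.append(
            DecompositionRow(
                variable=var,
                role=role,
                mean_x=mean_x,
                marginal_effect=ame[var],
                elasticity=eta,
                determinant_ci=ck,
                contribution=contrib,
                pct_contribution=(percentage_contribution(contrib, total)
                                  if total != 0 else float("nan")),
            )
        )

    explained = sum(r.contribution for r in rows)
    residual = total - explained
    need = sum(r.contribution for r in rows if r.role == "need")
    hi = total - need
    return DecompositionTable(
        rows=rows,
        total_index=total,
        residual=residual,
        hi=hi,
        hi_adjusted=hi / (1.0 - mu),
        mu=mu,
        n=len(y),
    )
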