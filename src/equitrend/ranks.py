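"""Weighted fractional ranks, concentration curves and concentration indices.

The concentration index family measures income-related inequality in a
health variable ``y``. Individuals are ranked from poorest to richest by a
living-standards variable (here household income per capita); each receives
a weighted fractional rank :math:`\\gamma_i \\in (0, 1)` whose weighted mean
is exactly 0.5. The covariance-scale ("generalized") index is

.. math:: GC = 2\\,\\mathrm{cov}_w(y, \\gamma),

the standard concentration index is :math:`C = GC/\\mu` with
:math:`\\mu = \\bar y_w`, and for a binary outcome the Wagstaff-normalized
index :math:`GC/(\\mu(1-\\mu)) = C/(1-\\mu)` is bounded in [−1, 1]. A
negative index means the outcome is concentrated among the poor
("pro-poor").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RankedOutcome",
    "IndexEstimate",
    "CurvePoints",
    "DegenerateDataWarning",
    "fractional_rank",
    "generalized_concentration_index",
    "concentration_index",
    "normalize_index",
    "index_confidence_limits",
    "concentration_curve",
    "curve_position",
]


class DegenerateDataWarning(UserWarning):
    """Raised-as-warning when data admit only a degenerate estimate."""


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        w = np.ones(n, dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}, got shape {w.shape}")
    if not np.all(w > 0):
        raise ValueError("all weights must be strictly positive")
    return w / w.sum()


def fractional_rank(ranking_var, weights=None) -> np.ndarray:
    """Weighted fractional ranks in (0, 1), midpoint convention.

    With observations sorted ascending by ``ranking_var`` and weights
    normalized to sum one, observation *i* receives the cumulative weight
    of everyone strictly poorer plus half its own weight. Tied values all
    receive the midpoint rank of their combined weight block. Ranks are
    returned in the original input order; their weighted mean is 0.5
    exactly (an algebraic identity, up to float rounding).
    """
    x = np.asarray(ranking_var, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("ranking_var must be a nonempty 1-d array")
    w = _as_weights(weights, x.size)

    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cum = np.concatenate(([0.0], np.cumsum(ws)))
    ranks_sorted = cum[:-1] + ws / 2.0

    # ties: every member of a tied block gets the block's midpoint rank
    # (block start cumweight + half the block's total weight)
    boundaries = np.concatenate(([True], xs[1:] != xs[:-1]))
    block_id = np.cumsum(boundaries) - 1
    block_start = cum[:-1][boundaries]
    block_w = np.bincount(block_id, weights=ws)
    ranks_sorted = block_start[block_id] + block_w[block_id] / 2.0

    out = np.empty_like(ranks_sorted)
    out[order] = ranks_sorted
    return out


@dataclass(frozen=True)
class RankedOutcome:
    """An outcome vector paired with fractional income ranks.

    Attributes
    ----------
    y : outcome values (binary in the utilization application).
    gamma : weighted fractional ranks in (0, 1).
    weights : sampling weights normalized to sum one.
    mu : weighted mean of ``y``.
    """

    y: np.ndarray
    gamma: np.ndarray
    weights: np.ndarray
    mu: float

    @classmethod
    def from_data(cls, y, ranking_var, weights=None) -> "RankedOutcome":
        y = np.asarray(y, dtype=float)
        w = _as_weights(weights, y.size)
        gamma = fractional_rank(ranking_var, w)
        return cls(y=y, gamma=gamma, weights=w, mu=float(w @ y))


def _resolve(y, gamma, weights):
    y = np.asarray(y, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if y.shape != gamma.shape:
        raise ValueError("y and gamma must have the same shape")
    if np.any((gamma <= 0) | (gamma >= 1)):
        raise ValueError("fractional ranks must lie strictly in (0, 1)")
    w = _as_weights(weights, y.size)
    return y, gamma, w


def generalized_concentration_index(y, gamma, weights=None) -> float:
    """Covariance-scale index ``2·cov_w(y, γ)`` (population covariance)."""
    y, gamma, w = _resolve(y, gamma, weights)
    mu = w @ y
    return float(2.0 * np.sum(w * (y - mu) * (gamma - 0.5)))


def concentration_index(y, gamma, weights=None) -> float:
    """Standard concentration index ``C = 2·cov_w(y, γ)/μ``.

    Raises
    ------
    ValueError
        If the weighted mean of ``y`` is zero (index undefined).
    """
    y, gamma, w = _resolve(y, gamma, weights)
    mu = float(w @ y)
    if mu == 0.0:
        raise ValueError("concentration index undefined: mean outcome is zero")
    return generalized_concentration_index(y, gamma, w) / mu


def normalize_index(index_value: float, mu: float, variant: str = "paper") -> float:
    """Rescale a concentration index for a binary outcome.

    Parameters
    ----------
    index_value
        ``variant="paper"``: the covariance-scale (generalized) index;
        ``"wagstaff_standard"`` and ``"erreygers"``: the standard index.
    mu
        Outcome prevalence, strictly inside (0, 1).
    variant
        ``"paper"`` divides by ``μ(1−μ)`` — the Wagstaff normalization
        applied to the covariance-scale index, algebraically identical to
        ``C_std/(1−μ)``. ``"wagstaff_standard"`` divides by ``1−μ``.
        ``"erreygers"`` multiplies by ``4μ``.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("normalization undefined: mu must lie strictly in (0, 1)")
    if variant == "paper":
        return index_value / (mu * (1.0 - mu))
    if variant == "wagstaff_standard":
        return index_value / (1.0 - mu)
    if variant == "erreygers":
        return 4.0 * mu * index_value
    raise ValueError(f"unknown normalization variant: {variant!r}")


@dataclass(frozen=True)
class IndexEstimate:
    """A concentration-index point estimate with symmetric confidence limits."""

    kind: str
    value: float
    std_error: float
    cl_lower: float
    cl_upper: float
    mu: float
    n: int


def _linearized_variance(y, gamma, w, mu, gc) -> float:
    # Taylor linearization of GC/mu with ranks treated as fixed: the
    # influence of observation i on C = 2 E_w[y(γ-1/2)]/μ is
    # (2/μ)(a_i − (GC/2μ)(y_i − μ)) with a_i = y_i(γ_i−1/2) − GC/2.
    a = y * (gamma - 0.5) - gc / 2.0
    u = (2.0 / mu) * (a - (gc / (2.0 * mu)) * (y - mu))
    return float(np.sum(w**2 * u**2))


def index_confidence_limits(
    y,
    gamma,
    weights=None,
    level: float = 0.95,
    method: str = "delta",
    kind: str = "standard",
    n_boot: int = 2000,
    seed=None,
) -> IndexEstimate:
    """Concentration index with a symmetric two-sided confidence interval.

    ``method="delta"`` uses a Taylor-linearization variance (equivalent to
    the robust standard error of the convenient regression of the rank on
    the transformed outcome); ``method="bootstrap"`` resamples observations
    with replacement, carrying their weights, with ``n_boot`` draws.
    ``kind`` selects the scale: ``"generalized"``, ``"standard"`` or
    ``"wagstaff"`` (binary-outcome normalization, bounded in [−1, 1]).
    """
    y, gamma, w = _resolve(y, gamma, weights)
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    mu = float(w @ y)

    def point(yv, gv, wv, muv):
        gc = float(2.0 * np.sum(wv * (yv - muv) * (gv - 0.5)))
        if kind == "generalized":
            return gc
        if kind == "standard":
            return gc / muv
        if kind == "wagstaff":
            return gc / (muv * (1.0 - muv))
        raise ValueError(f"unknown index kind: {kind!r}")

    if np.all(y == y[0]):
        warnings.warn(
            "outcome is constant: concentration index degenerate at zero",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return IndexEstimate(kind, 0.0, 0.0, 0.0, 0.0, mu, n)
    if kind in ("standard", "wagstaff") and (mu == 0.0 or (kind == "wagstaff" and mu >= 1.0)):
        raise ValueError("index undefined at degenerate prevalence")

    value = point(y, gamma, w, mu)
    z = stats.norm.ppf(0.5 + level / 2.0)

    if method == "delta":
        gc = float(2.0 * np.sum(w * (y - mu) * (gamma - 0.5)))
        var_std = _linearized_variance(y, gamma, w, mu, gc)
        if kind == "standard":
            se = np.sqrt(var_std)
        elif kind == "generalized":
            # IF of GC itself: 2(a_i) with a_i as above
            a = y * (gamma - 0.5) - gc / 2.0
            se = np.sqrt(float(np.sum(w**2 * (2.0 * a) ** 2)))
        else:  # wagstaff: C/(1-mu); propagate mu through 1/(1-mu) as well
            a = y * (gamma - 0.5) - gc / 2.0
            c = gc / mu
            u = (2.0 / mu) * (a - (gc / (2.0 * mu)) * (y - mu))
            u = u / (1.0 - mu) + c * (y - mu) / (1.0 - mu) ** 2
            se = np.sqrt(float(np.sum(w**2 * u**2)))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        reps = np.empty(n_boot)
        for b in range(n_boot):
            i = idx[b]
            wb = w[i] / w[i].sum()
            gb = fractional_rank(gamma[i], wb)  # re-rank the resample
            mub = float(wb @ y[i])
            reps[b] = point(y[i], gb, wb, mub)
        se = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown confidence-limit method: {method!r}")

    return IndexEstimate(
        kind=kind,
        value=float(value),
        std_error=float(se),
        cl_lower=float(value - z * se),
        cl_upper=float(value + z * se),
        mu=mu,
        n=n,
    )


@dataclass(frozen=True)
class CurvePoints:
    """A concentration curve: cumulative outcome share L against population share p."""

    p: np.ndarray
    L: np.ndarray


def concentration_curve(y, gamma, weights=None) -> CurvePoints:
    """Concentration curve at observation breakpoints, poorest to richest.

    L(p) is the cumulative weighted outcome share held by the poorest
    fraction p of the population; endpoints (0, 0) and (1, 1) included.
    """
    y, gamma, w = _resolve(y, gamma, weights)
    mu = float(w @ y)
    if mu == 0.0:
        raise ValueError("concentration curve undefined: mean outcome is zero")
    order = np.argsort(gamma, kind="stable")
    p = np.concatenate(([0.0], np.cumsum(w[order])))
    L = np.concatenate(([0.0], np.cumsum(w[order] * y[order]) / mu))
    p[-1] = 1.0
    L[-1] = 1.0
    return CurvePoints(p=p, L=L)


def curve_position(curve: CurvePoints, tolerance: float = 1e-9) -> str:
    """Classify a concentration curve against the equality diagonal.

    Returns ``"above"`` if L(p) ≥ p at every interior breakpoint with at
    least one strict excess beyond ``tolerance`` (pro-poor concentration),
    ``"below"`` for the mirror case, and ``"crossing"`` otherwise —
    including a curve lying on the diagonal everywhere (boundary
    convention: no strict side can be claimed).
    """
    d = curve.L[1:-1] - curve.p[1:-1]
    if d.size == 0:
        return "crossing"
    above = np.any(d > tolerance) and not np.any(d < -tolerance)
    below = np.any(d < -tolerance) and not np.any(d > tolerance)
    if above:
        return "above"
    if below:
        return "below"
    return "crossing"


def curve_area(curve: CurvePoints) -> float:
    """Trapezoid area under the concentration curve; C = 1 − 2·area."""
    return float(np.trapezoid(curve.L, curve.p))
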