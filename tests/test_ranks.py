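"""Fractional ranks, concentration indices/curves, and their identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equitrend.ranks import (
    DegenerateDataWarning,
    concentration_curve,
    concentration_index,
    curve_area,
    curve_position,
    fractional_rank,
    generalized_concentration_index,
    index_confidence_limits,
    normalize_index,
)
from tests.conftest import random_weighted_sample

# ---------------------------------------------------------------- oracles


def brute_force_ranks(values, weights):
    """Definitional weighted midpoint ranks via an O(n^2) scan."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out = np.empty_like(w)
    for i in range(len(values)):
        below = sum(w[j] for j in range(len(values)) if values[j] < values[i])
        tied = sum(w[j] for j in range(len(values)) if values[j] == values[i])
        out[i] = below + tied / 2.0
    return out


def brute_force_index(y, values, weights, kind):
    """Concentration indices from the definitional sums, independently."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    g = brute_force_ranks(values, w)
    mu = sum(w[i] * y[i] for i in range(len(y)))
    gbar = sum(w[i] * g[i] for i in range(len(y)))
    cov = sum(w[i] * (y[i] - mu) * (g[i] - gbar) for i in range(len(y)))
    if kind == "generalized":
        return 2.0 * cov
    if kind == "standard":
        return 2.0 * cov / mu
    return 2.0 * cov / (mu * (1.0 - mu))


# ------------------------------------------------------------ unit tests


@pytest.mark.parametrize(
    "values, weights, expected",
    [
        ([1, 2, 3, 4], None, [0.125, 0.375, 0.625, 0.875]),
        ([10, 20], [1, 3], [0.125, 0.625]),
        ([5, 5], None, [0.5, 0.5]),
        ([3, 1, 2], None, [5 / 6, 1 / 6, 3 / 6]),  # original order preserved
    ],
)
def test_fractional_rank_midpoint_convention(values, weights, expected):
    np.testing.assert_allclose(fractional_rank(values, weights), expected)


def test_fractional_rank_rejects_empty_and_bad_weights():
    with pytest.raises(ValueError):
        fractional_rank([])
    with pytest.raises(ValueError):
        fractional_rank([1, 2], [1, 0])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-1e6, 1e6, allow_nan=False),
            st.floats(0.01, 100.0, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_rank_mean_is_half_for_any_weights(data):
    """Weighted mean of fractional ranks is exactly 0.5, an algebraic identity."""
    values = [d[0] for d in data]
    weights = np.array([d[1] for d in data])
    g = fractional_rank(values, weights)
    assert abs(np.sum(weights / weights.sum() * g) - 0.5) < 1e-12
    assert np.all((g > 0) & (g < 1))


def test_generalized_index_hand_example():
    assert generalized_concentration_index([0, 1], [0.25, 0.75]) == pytest.approx(0.25)
    assert concentration_index([0, 1], [0.25, 0.75]) == pytest.approx(0.5)


def test_constant_outcome_gives_zero_index():
    g = fractional_rank([1, 2, 3])
    assert generalized_concentration_index([2, 2, 2], g) == pytest.approx(0.0)
    assert concentration_index([1, 1, 1], g) == pytest.approx(0.0)


def test_zero_mean_outcome_is_an_error():
    g = fractional_rank([1, 2, 3])
    with pytest.raises(ValueError, match="undefined"):
        concentration_index([0, 0, 0], g)
    with pytest.raises(ValueError):
        concentration_curve([0, 0, 0], g)


def test_antisymmetry_under_rank_reversal(rng):
    income, w, y = random_weighted_sample(rng, 200, mu_link=-0.5, slope=-1.0)
    g = fractional_rank(income, w)
    g_rev = fractional_rank(-income, w)
    assert concentration_index(y, g, w) == pytest.approx(
        -concentration_index(y, g_rev, w), abs=1e-12
    )


def test_scale_invariance_and_linearity(rng):
    income, w, y = random_weighted_sample(rng, 300, mu_link=-0.8, slope=0.7)
    g = fractional_rank(income, w)
    c = concentration_index(y, g, w)
    assert concentration_index(7.3 * y, g, w) == pytest.approx(c, abs=1e-12)
    gc = generalized_concentration_index(y, g, w)
    assert generalized_concentration_index(7.3 * y, g, w) == pytest.approx(
        7.3 * gc, abs=1e-10
    )


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    n=st.integers(2, 8),
    seed=st.integers(0, 10_000),
    kind=st.sampled_from(["generalized", "standard", "wagstaff"]),
)
def test_indices_match_brute_force_oracle_small_n(n, seed, kind):
    """All index variants equal an independent definitional computation, n<=8."""
    r = np.random.default_rng(seed)
    values = r.integers(0, 5, n).astype(float)  # ties likely
    w = r.uniform(0.2, 3.0, n)
    y = r.integers(0, 2, n).astype(float)
    if y.sum() == 0 or (kind == "wagstaff" and y.min() == y.max()):
        y[0] = 1.0
        y[-1] = 0.0 if n > 1 else y[-1]
    expected = brute_force_index(y, values, w, kind)
    g = fractional_rank(values, w)
    mu = float((w / w.sum()) @ y)
    got = generalized_concentration_index(y, g, w)
    if kind == "standard":
        got /= mu
    elif kind == "wagstaff":
        got /= mu * (1 - mu)
    assert got == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "value, mu, variant, expected",
    [
        (-0.0147, 0.0799, "paper", -0.2000),
        (-0.0676, 0.1863, "paper", -0.4459),
        (0.0, 0.3, "paper", 0.0),
        (0.0, 0.5, "erreygers", 0.0),
        (0.25, 0.5, "paper", 1.0),
        (-0.2, 0.5, "wagstaff_standard", -0.4),
        (0.1, 0.25, "erreygers", 0.1),
    ],
)
def test_normalize_index_variants(value, mu, variant, expected):
    assert normalize_index(value, mu, variant) == pytest.approx(expected, abs=5e-4)


def test_normalize_index_rejects_degenerate_mu():
    for mu in (0.0, 1.0, -0.1, 1.2):
        with pytest.raises(ValueError):
            normalize_index(0.1, mu)


def test_curve_matches_covariance_formula(rng):
    """1 − 2·area under the concentration curve equals the standard index."""
    for slope in (-1.2, 0.0, 1.5):
        income, w, y = random_weighted_sample(rng, 800, mu_link=-0.6, slope=slope)
        g = fractional_rank(income, w)
        c = concentration_index(y, g, w)
        area = curve_area(concentration_curve(y, g, w))
        assert 1.0 - 2.0 * area == pytest.approx(c, abs=1e-8)


def test_curve_endpoints_and_monotonicity(rng):
    income, w, y = random_weighted_sample(rng, 300, mu_link=-0.5, slope=-0.8)
    cur = concentration_curve(income, fractional_rank(income, w), w)
    assert cur.p[0] == 0.0 and cur.L[0] == 0.0
    assert cur.p[-1] == 1.0 and cur.L[-1] == 1.0
    assert np.all(np.diff(cur.L) >= -1e-12)
    assert np.all(np.diff(cur.p) > 0) or np.all(np.diff(cur.p) >= 0)


def test_curve_extreme_case_poorest_holds_everything():
    y = np.array([1.0, 0.0, 0.0, 0.0])
    income = np.array([1.0, 2.0, 3.0, 4.0])
    w = np.full(4, 0.25)
    cur = concentration_curve(y, fractional_rank(income, w), w)
    assert cur.L[1] == pytest.approx(1.0)
    assert cur.p[1] == pytest.approx(0.25)


def test_curve_position_classification():
    # diagonal: no strict side may be claimed
    g = fractional_rank([1.0, 2.0, 3.0, 4.0])
    flat = concentration_curve(np.ones(4), g)
    assert curve_position(flat) == "crossing"
    # outcome entirely with the poor -> above; mirrored -> below
    y = np.array([1.0, 1.0, 0.0, 0.0])
    above = concentration_curve(y, g)
    assert curve_position(above) == "above"
    below = concentration_curve(y[::-1], g)
    assert curve_position(below) == "below"


def test_curve_position_pro_poor_simulated(rng):
    income, w, y = random_weighted_sample(rng, 4000, mu_link=-0.8, slope=-1.2)
    cur = concentration_curve(y, fractional_rank(income, w), w)
    assert curve_position(cur, tolerance=0.01) == "above"


def test_wagstaff_bound_attained_and_respected(rng):
    # constructed extreme: the single rich observation holds the outcome
    g = np.array([0.25, 0.75])
    assert generalized_concentration_index([0, 1], g) / (0.5 * 0.5) == pytest.approx(1.0)
    for seed in range(5):
        r = np.random.default_rng(seed)
        income, w, y = random_weighted_sample(r, 500, mu_link=-0.5, slope=1.0)
        gam = fractional_rank(income, w)
        mu = float((w / w.sum()) @ y)
        wag = generalized_concentration_index(y, gam, w) / (mu * (1 - mu))
        assert -1.0 <= wag <= 1.0


def test_confidence_limits_degenerate_constant_outcome():
    g = fractional_rank([1.0, 2.0, 3.0])
    with pytest.warns(DegenerateDataWarning):
        est = index_confidence_limits(np.ones(3), g)
    assert (est.value, est.cl_lower, est.cl_upper) == (0.0, 0.0, 0.0)


def test_delta_and_bootstrap_limits_agree(rng):
    """Delta and bootstrap interval widths within 10% on an n=5000 cohort."""
    income, w, y = random_weighted_sample(rng, 5000, mu_link=-1.0, slope=-0.8)
    g = fractional_rank(income, w)
    delta = index_confidence_limits(y, g, w, method="delta")
    boot = index_confidence_limits(y, g, w, method="bootstrap", n_boot=2000, seed=7)
    assert delta.value == pytest.approx(boot.value)
    w_d = delta.cl_upper - delta.cl_lower
    w_b = boot.cl_upper - boot.cl_lower
    assert abs(w_d - w_b) / w_b < 0.10


def test_confidence_limit_ordering(rng):
    income, w, y = random_weighted_sample(rng, 400, mu_link=-0.9, slope=0.5)
    g = fractional_rank(income, w)
    for kind in ("generalized", "standard", "wagstaff"):
        est = index_confidence_limits(y, g, w, kind=kind)
        assert est.cl_lower <= est.value <= est.cl_upper
        assert est.std_error >= 0
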