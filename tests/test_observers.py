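"""Closed-form observer-model computations against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avci import (
    ObserverParams,
    discretize_response,
    final_estimates,
    fused_estimate,
    posterior_common_cause,
    segregated_estimates,
)
from avci.observers import InvalidParameterError

from conftest import random_params


# ---------------------------------------------------------------- oracles

def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def quadrature_posterior(x_a, x_v, p: ObserverParams, n_grid=200_001, half=150.0):
    """Posterior of a common cause by dense numerical integration over sources."""
    s = np.linspace(-half, half, n_grid)
    lik1 = np.trapezoid(_gauss(x_a, s, p.sigma_a) * _gauss(x_v, s, p.sigma_v)
                        * _gauss(s, p.mu_p, p.sigma_p), s)
    lik2 = (np.trapezoid(_gauss(x_a, s, p.sigma_a) * _gauss(s, p.mu_p, p.sigma_p), s)
            * np.trapezoid(_gauss(x_v, s, p.sigma_v) * _gauss(s, p.mu_p, p.sigma_p), s))
    num = lik1 * p.p_common
    return num / (num + lik2 * (1.0 - p.p_common))


def quadrature_fused_mean(x_a, x_v, p: ObserverParams, n_grid=200_001, half=150.0):
    """Posterior-mean source location under the common-cause structure."""
    s = np.linspace(-half, half, n_grid)
    w = _gauss(x_a, s, p.sigma_a) * _gauss(x_v, s, p.sigma_v) * _gauss(s, p.mu_p, p.sigma_p)
    return np.trapezoid(s * w, s) / np.trapezoid(w, s)


# ------------------------------------------------- posterior_common_cause

def test_posterior_prior_extremes(default_params):
    assert posterior_common_cause(3.0, -2.0, default_params.replace(p_common=1.0)) == 1.0
    assert posterior_common_cause(3.0, -2.0, default_params.replace(p_common=0.0)) == 0.0


@pytest.mark.parametrize("params", [
    ObserverParams(p_common=0.5, sigma_p=1.0, sigma_a=1.0, sigma_v=1.0),
    ObserverParams(p_common=0.5, sigma_p=12.0, sigma_a=6.0, sigma_v=1.5),
    ObserverParams(p_common=0.8, sigma_p=8.0, sigma_a=3.0, sigma_v=2.0, mu_p=0.0),
])
def test_posterior_matches_quadrature_oracle(params):
    """Closed-form marginals agree with dense numerical integration to 1e-6."""
    grid = np.linspace(-12.0, 12.0, 5)
    for x_a in grid:
        for x_v in grid:
            oracle = quadrature_posterior(x_a, x_v, params)
            closed = float(posterior_common_cause(x_a, x_v, params))
            assert closed == pytest.approx(oracle, abs=1e-6)


def test_posterior_equal_signals_unit_sigmas():
    p = ObserverParams(p_common=0.5, sigma_p=1.0, sigma_a=1.0, sigma_v=1.0)
    # frozen from the quadrature oracle at x_A = x_V = 0
    assert float(posterior_common_cause(0.0, 0.0, p)) == pytest.approx(
        0.5358983848622455, abs=1e-9)


def test_posterior_invalid_sigma_raises():
    with pytest.raises(InvalidParameterError):
        ObserverParams(sigma_a=-1.0)


# ------------------------------------------------------------- estimates

def test_fused_estimate_examples():
    p0 = ObserverParams(sigma_a=2.0, sigma_v=2.0, sigma_p=5.0, mu_p=0.0)
    assert float(fused_estimate(0.0, 0.0, p0)) == 0.0
    flat = ObserverParams(sigma_a=3.0, sigma_v=3.0, sigma_p=1e6)
    assert float(fused_estimate(9.0, 0.0, flat)) == pytest.approx(4.5, abs=1e-4)
    p = ObserverParams(sigma_a=6.0, sigma_v=1.5, sigma_p=12.0)
    direct = (9.0 / 36.0) / (1 / 36.0 + 1 / 2.25 + 1 / 144.0)
    assert float(fused_estimate(9.0, 0.0, p)) == pytest.approx(direct, rel=1e-12)
    assert float(fused_estimate(9.0, 0.0, p)) == pytest.approx(
        quadrature_fused_mean(9.0, 0.0, p), abs=1e-6)


def test_segregated_estimates_examples():
    p = ObserverParams(sigma_a=6.0, sigma_p=12.0, sigma_v=1.5)
    s_a, _ = segregated_estimates(9.0, 0.0, p)
    assert float(s_a) == pytest.approx(7.2, rel=1e-12)
    flat = p.replace(sigma_p=1e9)
    s_a, s_v = segregated_estimates(9.0, -3.0, flat)
    assert float(s_a) == pytest.approx(9.0, abs=1e-6)
    assert float(s_v) == pytest.approx(-3.0, abs=1e-6)
    s_a, _ = segregated_estimates(0.0, 5.0, p)
    assert float(s_a) == 0.0


# -------------------------------------------------------- final_estimates

def test_degenerate_prior_equivalences():
    """BCI collapses onto FF at p_common=1 and onto segregation at p_common=0."""
    rng = np.random.default_rng(1)
    x_a = rng.uniform(-20, 20, 1000)
    x_v = rng.uniform(-20, 20, 1000)
    base = ObserverParams(sigma_p=12.0, sigma_a=6.0, sigma_v=1.5)
    ff = final_estimates(x_a, x_v, base, "ff")
    bci1 = final_estimates(x_a, x_v, base.replace(p_common=1.0), "bci")
    np.testing.assert_allclose(bci1.s_hat_a, ff.s_hat_a, atol=1e-12)
    np.testing.assert_allclose(bci1.s_hat_v, ff.s_hat_v, atol=1e-12)
    bci0 = final_estimates(x_a, x_v, base.replace(p_common=0.0), "bci")
    seg_a, seg_v = segregated_estimates(x_a, x_v, base)
    np.testing.assert_allclose(bci0.s_hat_a, seg_a, atol=1e-12)
    np.testing.assert_allclose(bci0.s_hat_v, seg_v, atol=1e-12)


def test_fc_and_sf_limits():
    rng = np.random.default_rng(2)
    x_a = rng.uniform(-20, 20, 1000)
    x_v = rng.uniform(-20, 20, 1000)
    u = rng.random(1000)
    base = ObserverParams(sigma_p=12.0, sigma_a=6.0, sigma_v=1.5)
    ff = final_estimates(x_a, x_v, base, "ff")
    seg_a, seg_v = segregated_estimates(x_a, x_v, base)

    fc_inf = final_estimates(x_a, x_v, base.replace(k_c=1e12), "fc")
    np.testing.assert_allclose(fc_inf.s_hat_a, ff.s_hat_a, atol=1e-12)
    fc_zero = final_estimates(x_a, x_v, base.replace(k_c=0.0), "fc")
    off_diag = np.abs(x_a - x_v) > 0
    np.testing.assert_allclose(fc_zero.s_hat_a[off_diag], seg_a[off_diag], atol=1e-12)
    np.testing.assert_allclose(fc_zero.s_hat_v[off_diag], seg_v[off_diag], atol=1e-12)

    sf1 = final_estimates(x_a, x_v, base.replace(eta=1.0), "sf", fusion_draw=u)
    np.testing.assert_allclose(sf1.s_hat_a, ff.s_hat_a, atol=1e-12)
    sf0 = final_estimates(x_a, x_v, base.replace(eta=0.0), "sf", fusion_draw=u)
    np.testing.assert_allclose(sf0.s_hat_a, seg_a, atol=1e-12)


def test_fc_zero_criterion_segregates():
    p = ObserverParams(k_c=0.0, sigma_p=12.0, sigma_a=6.0, sigma_v=1.5)
    est = final_estimates(np.array([9.0]), np.array([0.0]), p, "fc")
    seg_a, _ = segregated_estimates(9.0, 0.0, p)
    assert est.s_hat_a[0] == pytest.approx(float(seg_a))
    assert est.posterior_c1[0] == 0.0


def test_sf_requires_fusion_draw():
    p = ObserverParams(eta=0.5)
    with pytest.raises(ValueError, match="fusion_draw"):
        final_estimates(np.zeros(3), np.zeros(3), p, "sf")


def test_sf_fusion_rate_binomial():
    """Fraction of fused trials tracks eta within 3 standard errors."""
    rng = np.random.default_rng(3)
    n = 10_000
    p = ObserverParams(eta=0.7, sigma_p=12.0, sigma_a=6.0, sigma_v=1.5)
    est = final_estimates(rng.normal(0, 5, n), rng.normal(0, 5, n), p,
                          "sf", fusion_draw=rng.random(n))
    frac = est.posterior_c1.mean()
    se = np.sqrt(0.7 * 0.3 / n)
    assert abs(frac - 0.7) < 3 * se


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_estimates_bounded_and_posterior_normalized(seed):
    """Final estimates stay within [min, max] of {x_A, x_V, mu_P}; posterior in [0,1]."""
    rng = np.random.default_rng(seed)
    params = random_params(rng)
    x_a = rng.uniform(-30, 30, 8)
    x_v = rng.uniform(-30, 30, 8)
    u = rng.random(8)
    lo = np.minimum.reduce([x_a, x_v, np.full(8, params.mu_p)])
    hi = np.maximum.reduce([x_a, x_v, np.full(8, params.mu_p)])
    for arch in ("bci", "ff", "fc", "sf"):
        est = final_estimates(x_a, x_v, params, arch, fusion_draw=u)
        assert np.all(est.posterior_c1 >= 0) and np.all(est.posterior_c1 <= 1)
        eps = 1e-9
        for out in (est.s_hat_a, est.s_hat_v, est.s_hat_c1):
            assert np.all(out >= lo - eps) and np.all(out <= hi + eps)


# ------------------------------------------------------------ discretize

@pytest.mark.parametrize("estimate,expected", [
    (0.0, 1), (5.0, 2), (-4.6, 0), (-4.5, 1), (4.5, 2), (4.4999, 1), (-100.0, 0),
])
def test_discretize_response(estimate, expected):
    assert discretize_response(estimate) == expected
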