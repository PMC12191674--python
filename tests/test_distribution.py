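"""Tests of the NAP-HL distribution: functions, moments, entropies, sampling."""

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from naphl import NapHL, hl_cdf, hl_pdf, hl_ppf

GRID_ALPHA = [0.3, 0.65, 1.25, 2.15, 5.0]
GRID_THETA = [0.45, 0.95, 1.65]


# -- half-logistic baseline -------------------------------------------------


def test_hl_basic_values():
    assert hl_cdf(0.0, 2.0) == 0.0
    assert hl_cdf(np.log(3.0), 1.0) == pytest.approx(0.5, abs=1e-14)
    total, _ = integrate.quad(lambda x: hl_pdf(x, 1.7), 0, np.inf)
    assert total == pytest.approx(1.0, abs=1e-8)
    assert hl_cdf(-1.0, 1.0) == 0.0 and hl_pdf(-1.0, 1.0) == 0.0


def test_hl_ppf_round_trip():
    u = np.linspace(0.01, 0.99, 25)
    assert np.allclose(hl_cdf(hl_ppf(u, 0.7), 0.7), u, atol=1e-12)


# -- distribution functions -------------------------------------------------


def test_cdf_survival_boundaries():
    d = NapHL(2.0, 1.0)
    assert d.cdf(0.0) == 0.0
    assert d.sf(0.0) == 1.0
    assert d.cdf(np.log(3.0)) == pytest.approx(2.0 - 2.0**0.75, abs=1e-12)


def test_hazard_quotient_identities(dist_11_06):
    x = np.linspace(0.05, 8.0, 100)
    f, F, S = dist_11_06.pdf(x), dist_11_06.cdf(x), dist_11_06.sf(x)
    assert np.allclose(dist_11_06.hazard(x), f / S, rtol=1e-12)
    assert np.allclose(dist_11_06.reverse_hazard(x), f / F, rtol=1e-12)
    assert np.allclose(dist_11_06.cumulative_hazard(x), -np.log(S), rtol=1e-12)


def test_hazard_signals_infinity_when_survival_underflows():
    d = NapHL(2.0, 1.0)
    assert d.hazard(1e5) == np.inf


@pytest.mark.parametrize("alpha", GRID_ALPHA)
@pytest.mark.parametrize("theta", GRID_THETA)
def test_pdf_normalisation(alpha, theta):
    d = NapHL(alpha, theta)
    total, _ = integrate.quad(lambda x: d.pdf(x), 0, d.ppf(1 - 1e-13), limit=200)
    assert total == pytest.approx(1.0, abs=1e-8)


def test_pdf_is_derivative_of_cdf(dist_11_06):
    x = np.linspace(0.1, 8.0, 150)
    eps = 1e-6
    num = (dist_11_06.cdf(x + eps) - dist_11_06.cdf(x - eps)) / (2 * eps)
    ana = dist_11_06.pdf(x)
    assert np.max(np.abs(num - ana) / ana) < 1e-6


def test_alpha_one_reduces_to_half_logistic():
    d = NapHL(1.0, 0.8)
    x = np.linspace(0.0, 10.0, 50)
    assert np.allclose(d.cdf(x), hl_cdf(x, 0.8), atol=1e-12)
    assert np.allclose(d.pdf(x), hl_pdf(x, 0.8), atol=1e-12)


# -- quantiles and sampling -------------------------------------------------


def test_quantile_round_trip():
    d = NapHL(2.0, 1.0)
    assert d.ppf(0.0) == 0.0
    assert d.ppf(1.0) == np.inf
    u = np.linspace(0.01, 0.99, 99)
    assert np.max(np.abs(d.cdf(d.ppf(u)) - u)) < 1e-9


def test_median_quantile_matches_bisection_oracle():
    d = NapHL(2.0, 1.0)
    root = optimize.brentq(lambda x: d.cdf(x) - 0.5, 1e-9, 50.0, xtol=1e-12)
    assert root == pytest.approx(1.53076, abs=1e-5)
    assert d.ppf(0.5) == pytest.approx(root, abs=1e-9)


def test_quantile_domain_error():
    with pytest.raises(ValueError):
        NapHL(2.0, 1.0).ppf(1.5)


def test_scale_family_in_theta():
    u = np.linspace(0.05, 0.95, 10)
    for theta in GRID_THETA:
        assert np.allclose(
            NapHL(1.7, theta).ppf(u), np.asarray(NapHL(1.7, 1.0).ppf(u)) / theta,
            rtol=1e-12,
        )
    s1 = NapHL(1.1, 0.6).moment_summary()
    s2 = NapHL(1.1, 2.8).moment_summary()
    assert s1.skewness == pytest.approx(s2.skewness, abs=1e-6)
    assert s1.kurtosis == pytest.approx(s2.kurtosis, abs=1e-5)


def test_rvs_deterministic_positive_and_distributed(dist_11_06):
    a = dist_11_06.rvs(5000, seed=42)
    b = dist_11_06.rvs(5000, seed=42)
    assert np.array_equal(a, b)
    assert np.all(a > 0)
    # marginal law: K-S against the model CDF
    assert stats.kstest(a, dist_11_06.cdf).pvalue > 0.01
    # mean within 3 standard errors of the quadrature mean
    mu = dist_11_06.raw_moment(1)
    se = a.std(ddof=1) / np.sqrt(a.size)
    assert abs(a.mean() - mu) < 3 * se


def test_rvs_domain_error(dist_11_06):
    with pytest.raises(ValueError):
        dist_11_06.rvs(0)


# -- moments and related ----------------------------------------------------


def test_raw_moment_conventions(dist_11_06):
    assert dist_11_06.raw_moment(0) == 1.0
    with pytest.raises(ValueError):
        dist_11_06.raw_moment(-1)
    with pytest.raises(ValueError):
        dist_11_06.raw_moment(1.5)


def test_mgf_properties(dist_11_06):
    assert dist_11_06.mgf(0.0) == pytest.approx(1.0, abs=1e-12)
    eps = 1e-4
    dmgf = (dist_11_06.mgf(eps) - dist_11_06.mgf(-eps)) / (2 * eps)
    assert dmgf == pytest.approx(dist_11_06.raw_moment(1), abs=1e-4)
    quad_val, _ = integrate.quad(
        lambda x: np.exp(0.1 * x) * dist_11_06.pdf(x), 0, dist_11_06.ppf(1 - 1e-13)
    )
    assert dist_11_06.mgf(0.1, r_max=30) == pytest.approx(quad_val, abs=1e-5)
    with pytest.raises(ValueError):
        dist_11_06.mgf(0.6)  # at the tail rate: series diverges


def test_incomplete_moment(dist_11_06):
    assert dist_11_06.incomplete_moment(1, 0.0) == 0.0
    full = dist_11_06.incomplete_moment(1, np.inf)
    assert full == pytest.approx(dist_11_06.raw_moment(1), abs=1e-8)
    med = dist_11_06.median()
    assert dist_11_06.incomplete_moment(1, med) < dist_11_06.raw_moment(1)
    z = np.linspace(0.5, 5.0, 8)
    vals = [dist_11_06.incomplete_moment(1, zi) for zi in z]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        dist_11_06.incomplete_moment(1, -1.0)


def test_mrl_mwt_total_expectation_identity(dist_11_06):
    assert dist_11_06.mean_residual_life(0.0) == pytest.approx(
        dist_11_06.raw_moment(1), abs=1e-7
    )
    assert dist_11_06.mean_waiting_time(1e-6) < 1e-3
    t = dist_11_06.median()
    F, S = dist_11_06.cdf(t), dist_11_06.sf(t)
    lhs = F * (t - dist_11_06.mean_waiting_time(t)) + S * (
        t + dist_11_06.mean_residual_life(t)
    )
    assert lhs == pytest.approx(dist_11_06.raw_moment(1), abs=1e-6)


def test_mrl_undefined_beyond_support():
    d = NapHL(2.0, 1.0)
    with pytest.raises(ValueError):
        d.mean_residual_life(1e6)


# -- entropies ---------------------------------------------------------------


@pytest.mark.parametrize("phi", [1.5, 2.0, 2.75])
@pytest.mark.parametrize("alpha,theta", [(1.1, 0.6), (2.6, 2.8)])
def test_renyi_tsallis_identity(alpha, theta, phi):
    d = NapHL(alpha, theta)
    R, Q = d.renyi_entropy(phi), d.tsallis_entropy(phi)
    assert Q == pytest.approx((1 - np.exp((1 - phi) * R)) / (phi - 1), abs=1e-10)


def test_entropy_domain_errors(dist_11_06):
    for bad in (0.0, -1.0, 1.0):
        with pytest.raises(ValueError):
            dist_11_06.renyi_entropy(bad)


# -- order statistics --------------------------------------------------------


def test_order_statistic_pdf(dist_11_06):
    x = np.linspace(0.2, 6.0, 20)
    assert np.allclose(
        dist_11_06.order_statistic_pdf(x, 1, 1), dist_11_06.pdf(x), rtol=1e-12
    )
    total, _ = integrate.quad(
        lambda t: dist_11_06.order_statistic_pdf(t, 2, 5), 0, dist_11_06.ppf(1 - 1e-13),
        limit=200,
    )
    assert total == pytest.approx(1.0, abs=1e-6)
    # maximum of 5 draws has the closed form 5 f F^4
    expected = 5 * np.asarray(dist_11_06.pdf(x)) * np.asarray(dist_11_06.cdf(x)) ** 4
    assert np.allclose(dist_11_06.order_statistic_pdf(x, 5, 5), expected, rtol=1e-12)
    with pytest.raises(ValueError):
        dist_11_06.order_statistic_pdf(1.0, 6, 5)


# -- series expansion --------------------------------------------------------


def test_series_leading_coefficient(dist_11_06):
    sc = dist_11_06.series_coefficients(0, 0, 0)
    assert sc.delta[0, 0, 0] == pytest.approx(np.log(1.1), abs=1e-14)
    # zero truncation yields a single exponential term
    x = np.array([0.5, 1.0, 2.0])
    expected = sc.prefactor * sc.delta[0, 0, 0] * np.exp(-0.6 * x)
    assert np.allclose(sc.pdf(x), expected, rtol=1e-12)


def test_series_matches_closed_form_density(dist_11_06):
    x = np.linspace(0.5, 5.0, 40)
    dev = np.abs(dist_11_06.series_pdf(x, 40, 40, 40) - dist_11_06.pdf(x))
    assert np.max(dev) < 1e-3


def test_series_invalid_at_alpha_one():
    with pytest.raises(ValueError):
        NapHL(1.0, 1.0).series_coefficients(5, 5, 5)


def test_invalid_parameters_raise():
    for a, t in [(0.0, 1.0), (-2.0, 1.0), (1.0, 0.0), (1.0, -3.0)]:
        with pytest.raises(ValueError):
            NapHL(a, t)
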