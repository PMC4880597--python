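"""The sixteen-family registry: densities, CDFs, quantiles, sampling, support."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import axondist as ad
from axondist.families import FAMILY_NAMES, get_family

EXPECTED_N_PARAMS = {
    "exponential": 1,
    "rayleigh": 1,
    "generalized_extreme_value": 3,
    "generalized_pareto": 3,
    "t_location_scale": 3,
}

# one representative, axon-scale parameter vector per family
REP_PARAMS = {
    "birnbaum_saunders": (0.5, 0.5),
    "exponential": (2.0,),
    "extreme_value": (0.5, 0.2),
    "gamma": (4.0, 0.14),
    "generalized_extreme_value": (0.45, 0.15, 0.2),
    "generalized_pareto": (0.2, 0.05, 0.3),
    "inverse_gaussian": (0.56, 1.5),
    "log_logistic": (0.5, 4.0),
    "log_normal": (-0.7, 0.5),
    "logistic": (0.55, 0.15),
    "nakagami": (1.5, 0.4),
    "normal": (0.56, 0.27),
    "rayleigh": (0.4,),
    "rician": (0.5, 0.2),
    "t_location_scale": (5.0, 0.2, 0.5),
    "weibull": (0.6, 2.0),
}


def test_registry_matches_study_design():
    """Sixteen uniquely named families with the documented parameter counts."""
    assert len(FAMILY_NAMES) == 16
    assert len(set(FAMILY_NAMES)) == 16
    for name in FAMILY_NAMES:
        fam = get_family(name)
        assert fam.n_params == len(fam.param_names)
        assert fam.n_params == EXPECTED_N_PARAMS.get(name, 2)


@pytest.mark.parametrize(
    "family, params, x, expected",
    [
        ("exponential", (1.0,), 0.0, 1.0),  # f(0) = lambda
        ("normal", (0.0, 1.0), 0.0, 1.0 / math.sqrt(2 * math.pi)),
    ],
)
def test_pdf_known_points(family, params, x, expected):
    assert get_family(family).pdf(params, x) == pytest.approx(expected, rel=1e-12)


def test_gamma_shape_one_is_exponential():
    g, e = get_family("gamma"), get_family("exponential")
    x = np.linspace(0.01, 5, 50)
    np.testing.assert_allclose(g.pdf((1.0, 2.0), x), e.pdf((0.5,), x), rtol=1e-12)


@pytest.mark.parametrize(
    "family, params, other, other_params",
    [
        ("weibull", (2.0, 1.0), "exponential", (0.5,)),
        ("nakagami", (1.0, 0.5), "rayleigh", (0.5,)),  # sigma = sqrt(Omega/2)
        ("rician", (1e-9, 0.7), "rayleigh", (0.7,)),
    ],
)
def test_special_case_collapses(family, params, other, other_params):
    """Families that contain simpler families as exact special cases."""
    x = np.linspace(0.05, 3, 40)
    np.testing.assert_allclose(
        get_family(family).pdf(params, x),
        get_family(other).pdf(other_params, x),
        rtol=1e-6,
    )


def test_t_large_df_approaches_normal():
    x = np.linspace(-2, 2, 30)
    t = get_family("t_location_scale").pdf((1e6, 1.0, 0.0), x)
    n = get_family("normal").pdf((0.0, 1.0), x)
    np.testing.assert_allclose(t, n, atol=1e-3)


def test_gev_shape_zero_limit_is_gumbel():
    """As xi -> 0 the GEV density approaches the maximum-type Gumbel form."""
    mu, sigma = 0.4, 0.2
    x = np.linspace(-0.5, 2.0, 60)
    z = (x - mu) / sigma
    gumbel = np.exp(-z - np.exp(-z)) / sigma
    gev = get_family("generalized_extreme_value").pdf((mu, sigma, 1e-8), x)
    np.testing.assert_allclose(gev, gumbel, rtol=1e-5)


def test_extreme_value_is_minimum_type():
    """The two-parameter extreme value family is the left-skewed (minima) Gumbel."""
    fam = get_family("extreme_value")
    assert fam.sample((0.0, 1.0), 20000, seed=1).mean() < -0.4  # mean = -Euler gamma
    # left tail heavier than right
    assert fam.pdf((0.0, 1.0), -3.0) > fam.pdf((0.0, 1.0), 3.0)


@pytest.mark.parametrize(
    "family, params, x, expected",
    [
        ("exponential", (2.0,), math.log(2) / 2.0, 0.5),
        ("normal", (0.0, 1.0), 0.0, 0.5),
    ],
)
def test_cdf_known_points(family, params, x, expected):
    assert get_family(family).cdf(params, x) == pytest.approx(expected, rel=1e-12)


def test_birnbaum_saunders_cdf_is_probit_form():
    """BS CDF equals Phi((sqrt(x/b) - sqrt(b/x)) / g), checked vs quadrature."""
    beta, gamma = 0.5, 0.6
    fam = get_family("birnbaum_saunders")
    for x in (0.2, 0.5, 1.1):
        closed = stats.norm.cdf((math.sqrt(x / beta) - math.sqrt(beta / x)) / gamma)
        assert fam.cdf((beta, gamma), x) == pytest.approx(closed, abs=1e-12)
        quad, _ = integrate.quad(lambda t: fam.pdf((beta, gamma), t), 0, x)
        assert fam.cdf((beta, gamma), x) == pytest.approx(quad, abs=1e-8)


def test_gev_quantile_closed_form():
    mu, sigma, xi = 0.0, 1.0, 0.5
    p = math.exp(-1.0)
    closed = mu + sigma * ((-math.log(p)) ** (-xi) - 1.0) / xi
    fam = get_family("generalized_extreme_value")
    assert fam.quantile((mu, sigma, xi), p) == pytest.approx(closed, rel=1e-9)
    # bisection oracle on the cdf
    from scipy.optimize import brentq

    root = brentq(lambda x: fam.cdf((mu, sigma, xi), x) - p, -1.9, 50)
    assert root == pytest.approx(closed, abs=1e-8)


@pytest.mark.parametrize("family", FAMILY_NAMES)
def test_quantile_cdf_round_trip(family):
    fam = get_family(family)
    params = REP_PARAMS[family]
    x = fam.quantile(params, np.linspace(0.01, 0.99, 9))  # support interior
    np.testing.assert_allclose(fam.quantile(params, fam.cdf(params, x)), x, atol=1e-6)
    p = np.array([0.05, 0.5, 0.95])
    q = fam.quantile(params, p)
    assert np.all(np.diff(q) > 0)
    np.testing.assert_allclose(fam.cdf(params, q), p, atol=1e-9)


def test_quantile_rejects_degenerate_probabilities():
    with pytest.raises(ValueError):
        get_family("exponential").quantile((1.0,), 0.0)
    with pytest.raises(ValueError):
        get_family("normal").quantile((0.0, 1.0), 1.0)


@pytest.mark.parametrize("family", FAMILY_NAMES)
def test_normalization_over_random_parameters(family):
    """Every density integrates to one across randomized valid parameters."""
    fam = get_family(family)
    rng = np.random.default_rng(2024)
    for _ in range(5):
        params = ad.random_feasible_params(family, rng)
        frozen = fam.frozen(params)
        lo, hi = frozen.support()
        mid = frozen.median()
        total = (
            integrate.quad(frozen.pdf, lo, mid, limit=200)[0]
            + integrate.quad(frozen.pdf, mid, hi, limit=200)[0]
        )
        assert total == pytest.approx(1.0, abs=1e-6), params


@pytest.mark.parametrize("family", FAMILY_NAMES)
def test_cdf_derivative_matches_pdf(family):
    fam = get_family(family)
    params = REP_PARAMS[family]
    lo, hi = fam.support(params)
    x = np.linspace(max(lo, -2) + 0.1, min(hi, 3) - 0.1, 15)
    h = 1e-5
    deriv = (fam.cdf(params, x + h) - fam.cdf(params, x - h)) / (2 * h)
    pdf = fam.pdf(params, x)
    mask = pdf > 1e-5  # far tails saturate the CDF in double precision
    np.testing.assert_allclose(deriv[mask], pdf[mask], rtol=1e-4)


@pytest.mark.parametrize("family", FAMILY_NAMES)
def test_logpdf_consistent_with_pdf(family):
    fam = get_family(family)
    params = REP_PARAMS[family]
    lo, hi = fam.support(params)
    x = np.linspace(max(lo, -2) + 0.05, min(hi, 4) - 0.05, 25)
    pdf = fam.pdf(params, x)
    mask = pdf > 1e-300
    np.testing.assert_allclose(
        np.exp(fam.logpdf(params, x[mask])), pdf[mask], rtol=1e-12
    )


def test_rician_logpdf_stable_at_high_snr():
    """Large noncentrality must not overflow the Bessel term."""
    val = get_family("rician").logpdf((200.0, 1.0), 200.0)
    assert np.isfinite(val)
    # Gaussian limit: rice(nu, sigma) -> N(sqrt(nu^2+sigma^2), sigma) for nu >> sigma
    assert val == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)), abs=1e-2)


def test_sampling_is_seeded_and_converges():
    fam = get_family("log_normal")
    a = fam.sample((-0.7, 0.5), 5, seed=9)
    b = fam.sample((-0.7, 0.5), 5, seed=9)
    np.testing.assert_array_equal(a, b)
    big = fam.sample((-0.7, 0.5), 100_000, seed=10)
    ks = stats.kstest(big, fam.frozen((-0.7, 0.5)).cdf).statistic
    assert ks < 0.01


def test_rayleigh_sample_mean_matches_moment():
    sigma = 1.0
    x = get_family("rayleigh").sample((sigma,), 100_000, seed=5)
    mean = sigma * math.sqrt(math.pi / 2)
    se = sigma * math.sqrt((4 - math.pi) / 2) / math.sqrt(x.size)
    assert abs(x.mean() - mean) < 3 * se


@pytest.mark.parametrize(
    "family, params, expected_lo, expected_hi",
    [
        ("generalized_extreme_value", (0.0, 1.0, 0.5), -2.0, math.inf),
        ("generalized_extreme_value", (0.0, 1.0, -0.5), -math.inf, 2.0),
        ("generalized_pareto", (0.5, 0.1, 1.0), 0.1, math.inf),
        ("generalized_pareto", (-0.5, 0.0, 1.0), 0.0, 2.0),
        ("exponential", (1.0,), 0.0, math.inf),
        ("normal", (0.0, 1.0), -math.inf, math.inf),
        ("log_normal", (0.0, 1.0), 0.0, math.inf),
    ],
)
def test_support_bounds(family, params, expected_lo, expected_hi):
    lo, hi = get_family(family).support(params)
    assert lo == pytest.approx(expected_lo)
    assert hi == pytest.approx(expected_hi)


def test_pdf_zero_outside_support():
    gev = get_family("generalized_extreme_value")
    assert gev.pdf((0.0, 1.0, 0.5), -3.0) == 0.0
    assert gev.logpdf((0.0, 1.0, 0.5), -3.0) == -math.inf
    assert get_family("weibull").pdf((1.0, 2.0), -1.0) == 0.0


@pytest.mark.parametrize(
    "family, bad_params",
    [
        ("exponential", (-1.0,)),
        ("normal", (0.0, 0.0)),
        ("nakagami", (0.3, 1.0)),  # m >= 1/2 required
        ("t_location_scale", (0.0, 1.0, 0.0)),
        ("gamma", (2.0,)),  # wrong arity
        ("rician", (-0.1, 1.0)),
    ],
)
def test_invalid_parameters_raise(family, bad_params):
    with pytest.raises(ad.ParameterError):
        get_family(family).pdf(bad_params, 1.0)


def test_unknown_family_raises():
    with pytest.raises(KeyError):
        get_family("beta")


# -- property-based invariants ------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    rate=st.floats(0.05, 50.0),
    p=st.floats(0.001, 0.999),
)
def test_exponential_quantile_closed_form_property(rate, p):
    """Quantile inverts the CDF: q(p) = -ln(1-p)/rate for every valid rate."""
    fam = get_family("exponential")
    assert fam.quantile((rate,), p) == pytest.approx(-math.log1p(-p) / rate, rel=1e-9)
    assert fam.cdf((rate,), fam.quantile((rate,), p)) == pytest.approx(p, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    mu=st.floats(-1.0, 2.0),
    sigma=st.floats(0.05, 2.0),
    xi=st.floats(-0.45, 0.9),
)
def test_gev_support_rule_property(mu, sigma, xi):
    """GEV support is bounded below (xi>0), above (xi<0), by mu - sigma/xi."""
    lo, hi = get_family("generalized_extreme_value").support((mu, sigma, xi))
    if xi == 0.0:  # Gumbel limit: unbounded support
        assert lo == -math.inf and hi == math.inf
        return
    bound = mu - sigma / xi
    if xi > 0:
        assert lo == pytest.approx(bound) and hi == math.inf
    else:
        assert lo == -math.inf and hi == pytest.approx(bound)
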