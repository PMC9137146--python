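"""Copula calibration, structural properties and sampling checks."""

import numpy as np
import pytest
from scipy import stats

from copulabv.copulas import (
    CopulaSpec,
    conditional_cdf,
    copula_cdf,
    copula_logpdf,
    gaussian_margins,
    kendall_tau_of,
    pearson_from_copula,
    sample_pairs,
    tail_dependence,
    tau_to_theta,
)

FAMILIES = ("normal", "frank", "clayton", "joe")


# -- parameter calibration --------------------------------------------------

@pytest.mark.parametrize("family,tau,theta", [
    ("clayton", 0.4, 2 * 0.4 / 0.6),          # theta = 2 tau / (1 - tau)
    ("clayton", 0.7, 2 * 0.7 / 0.3),
    ("frank", 0.4, 4.161064),
    ("frank", 0.7, 11.411540),
    ("joe", 0.4, 2.219070),      # roots of the series form of Joe's tau
    ("joe", 0.7, 5.4637566),
    ("normal", 0.4, np.sin(np.pi * 0.2)),     # rho = sin(pi tau / 2)
])
def test_tau_to_theta(family, tau, theta):
    assert tau_to_theta(family, tau) == pytest.approx(theta, abs=5e-6)


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.2, 0.4, 0.7, -0.4, -0.7])
def test_tau_round_trip(family, tau):
    spec = CopulaSpec.from_tau(family, tau)
    assert kendall_tau_of(spec, method="closed") == pytest.approx(tau, abs=1e-8)


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.7])
def test_tau_integral_oracle(family, tau):
    """tau = 4 E[C(U,V)] - 1 evaluated by quadrature agrees with the
    closed-form calibration."""
    spec = CopulaSpec.from_tau(family, tau)
    assert kendall_tau_of(spec, method="integral", n_grid=400) == pytest.approx(
        tau, abs=2e-3)


def test_rotation_flag():
    assert CopulaSpec.from_tau("clayton", -0.4).rotated_270
    assert CopulaSpec.from_tau("joe", -0.7).rotated_270
    assert not CopulaSpec.from_tau("frank", -0.4).rotated_270
    assert not CopulaSpec.from_tau("clayton", 0.4).rotated_270


def test_invalid_specs():
    with pytest.raises(ValueError):
        CopulaSpec.from_tau("gumbel", 0.4)
    with pytest.raises(ValueError):
        CopulaSpec.from_tau("normal", 1.0)


# -- CDF structure ----------------------------------------------------------

@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.7])
def test_cdf_boundaries_and_frechet(family, tau):
    spec = CopulaSpec.from_tau(family, tau)
    u = np.linspace(0.0, 1.0, 21)
    assert np.allclose(copula_cdf(spec, u, np.zeros_like(u)), 0.0, atol=1e-12)
    assert np.allclose(copula_cdf(spec, np.zeros_like(u), u), 0.0, atol=1e-12)
    assert np.allclose(copula_cdf(spec, u, np.ones_like(u)), u, atol=1e-9)
    assert np.allclose(copula_cdf(spec, np.ones_like(u), u), u, atol=1e-9)
    gu, gv = np.meshgrid(u, u)
    C = copula_cdf(spec, gu, gv)
    lower = np.maximum(gu + gv - 1.0, 0.0)
    upper = np.minimum(gu, gv)
    assert np.all(C >= lower - 1e-9)
    assert np.all(C <= upper + 1e-9)


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.4])
def test_cdf_two_increasing(family, tau):
    spec = CopulaSpec.from_tau(family, tau)
    rng = np.random.default_rng(5)
    a, b = np.sort(rng.uniform(size=(2, 200)), axis=0)
    c, d = np.sort(rng.uniform(size=(2, 200)), axis=0)
    vol = (copula_cdf(spec, b, d) - copula_cdf(spec, a, d)
           - copula_cdf(spec, b, c) + copula_cdf(spec, a, c))
    assert np.all(vol >= -1e-10)


def test_clayton_cdf_value():
    """(u^-theta + v^-theta - 1)^(-1/theta) at u = v = 0.5, theta = 2."""
    spec = CopulaSpec(family="clayton", kendall_tau=0.5, rotated_270=False)
    assert spec.theta == pytest.approx(2.0)
    assert copula_cdf(spec, 0.5, 0.5) == pytest.approx(7.0 ** -0.5, abs=1e-9)


# -- density and conditional ------------------------------------------------

@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.7])
def test_density_integrates_to_cdf(family, tau):
    """The density integrated over [0, u] x [0, v] recovers the CDF."""
    spec = CopulaSpec.from_tau(family, tau)
    x, w = np.polynomial.legendre.leggauss(80)
    for (u, v) in [(0.4, 0.6), (0.8, 0.3)]:
        gx = 0.5 * u * (x + 1.0)
        gy = 0.5 * v * (x + 1.0)
        wu, wv = 0.5 * u * w, 0.5 * v * w
        uu, vv = np.meshgrid(gx, gy, indexing="ij")
        dens = np.exp(copula_logpdf(spec, uu, vv))
        approx = float(wu @ dens @ wv)
        assert approx == pytest.approx(float(copula_cdf(spec, u, v)), abs=2e-4)


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.7])
def test_conditional_cdf_matches_finite_difference(family, tau):
    spec = CopulaSpec.from_tau(family, tau)
    u = np.array([0.2, 0.5, 0.8])
    v = np.array([0.3, 0.6, 0.9])
    h = 1e-6
    fd = (copula_cdf(spec, u + h, v) - copula_cdf(spec, u - h, v)) / (2 * h)
    assert np.allclose(conditional_cdf(spec, u, v), fd, atol=1e-5)


@pytest.mark.parametrize("family", FAMILIES)
def test_conditional_cdf_is_distribution(family):
    spec = CopulaSpec.from_tau(family, 0.6)
    u = np.full(99, 0.37)
    v = np.linspace(0.01, 0.99, 99)
    h = conditional_cdf(spec, u, v)
    assert np.all(np.diff(h) > 0)
    assert np.all((h > 0) & (h < 1))


# -- sampling ---------------------------------------------------------------

@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("tau", [0.4, -0.7])
def test_sampling_tau_and_margins(family, tau):
    spec = CopulaSpec.from_tau(family, tau)
    rng = np.random.default_rng(123)
    pairs = sample_pairs(spec, 20000, rng)
    assert pairs.shape == (20000, 2)
    assert np.all((pairs > 0) & (pairs < 1))
    emp_tau = stats.kendalltau(pairs[:, 0], pairs[:, 1]).statistic
    assert emp_tau == pytest.approx(tau, abs=0.02)
    for col in range(2):
        assert stats.kstest(pairs[:, col], "uniform").pvalue > 1e-4


def test_gaussian_margins_rejects_boundary():
    with pytest.raises(ValueError):
        gaussian_margins(np.array([[0.0, 0.5]]))
    x = gaussian_margins(np.array([[0.5, 0.975]]))
    assert x[0, 0] == pytest.approx(0.0)
    assert x[0, 1] == pytest.approx(1.959964, abs=1e-5)


# -- induced Pearson correlation and tails ----------------------------------

def test_pearson_normal_is_closed_form():
    for tau in (0.2, 0.4, -0.4):
        spec = CopulaSpec.from_tau("normal", tau)
        assert pearson_from_copula(spec) == pytest.approx(
            np.sin(np.pi * tau / 2.0), abs=1e-9)


def test_pearson_sign_flips_under_rotation():
    pos = pearson_from_copula(CopulaSpec.from_tau("clayton", 0.4))
    neg = pearson_from_copula(CopulaSpec.from_tau("clayton", -0.4))
    assert neg == pytest.approx(-pos, abs=1e-9)


def test_pearson_monte_carlo_cross_check():
    spec = CopulaSpec.from_tau("joe", 0.7)
    rng = np.random.default_rng(7)
    x = gaussian_margins(sample_pairs(spec, 200000, rng))
    mc = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
    assert pearson_from_copula(spec) == pytest.approx(mc, abs=0.01)


def test_tail_dependence():
    lam = tail_dependence(CopulaSpec.from_tau("clayton", 0.7))
    theta = 2 * 0.7 / 0.3
    assert lam == pytest.approx((2.0 ** (-1.0 / theta), 0.0), abs=1e-9)
    assert lam[0] == pytest.approx(0.86, abs=5e-3)
    lj = tail_dependence(CopulaSpec.from_tau("joe", 0.7))
    assert lj[0] == 0.0 and lj[1] == pytest.approx(
        2.0 - 2.0 ** (1.0 / tau_to_theta("joe", 0.7)), abs=1e-9)
    assert tail_dependence(CopulaSpec.from_tau("frank", 0.7)) == (0.0, 0.0)
    assert tail_dependence(CopulaSpec.from_tau("normal", 0.7)) == (0.0, 0.0)
    # rotation moves mass to the off-corners: no L/U tail dependence remains
    assert tail_dependence(CopulaSpec.from_tau("clayton", -0.7)) == (0.0, 0.0)
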