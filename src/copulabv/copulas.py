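"""Bivariate copulas for residual dependence structures.

Implements the normal, Frank, Clayton and Joe families (and their 270-degree
rotations, used to express negative Kendall correlation with the Clayton and
Joe families, which are only defined for positive dependence).  A copula is
the CDF on the unit square that links the two marginal CDFs of a continuous
random pair to its joint CDF (Sklar's theorem), so it carries the full
dependence structure separately from the margins.

The module exposes

* parameterisation by Kendall's tau (:func:`tau_to_theta`,
  :func:`kendall_tau_of`),
* evaluation (:func:`copula_cdf`, :func:`copula_logpdf`),
* conditional-inversion sampling (:func:`sample_pairs`),
* the Pearson correlation induced on standard-normal margins
  (:func:`pearson_from_copula`, via 2-D quadrature except for the normal
  family where it is sin(pi*tau/2)),
* tail-dependence coefficients (:func:`tail_dependence`),
* the probability-integral transform to Gaussian margins
  (:func:`gaussian_margins`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "FAMILIES",
    "CopulaSpec",
    "tau_to_theta",
    "kendall_tau_of",
    "copula_cdf",
    "copula_logpdf",
    "conditional_cdf",
    "sample_pairs",
    "gaussian_margins",
    "pearson_from_copula",
    "tail_dependence",
]

FAMILIES = ("normal", "frank", "clayton", "joe")

_INV_TOL = 1e-8          # tolerance for tau -> theta numeric inversion
_COND_TOL = 1e-10        # tolerance of the conditional-quantile root find
_EPS = 1e-12             # open-interval guard for u, v


def _validate_theta(family: str, theta: float) -> None:
    if family == "normal":
        if not -1.0 < theta < 1.0:
            raise ValueError(f"normal copula requires rho in (-1, 1), got {theta}")
    elif family == "frank":
        if theta == 0.0:
            raise ValueError("frank copula requires theta != 0")
    elif family == "clayton":
        if not (-1.0 <= theta < 0.0 or theta > 0.0):
            raise ValueError(f"clayton copula requires theta in [-1,0) or (0,inf), got {theta}")
    elif family == "joe":
        if theta < 1.0:
            raise ValueError(f"joe copula requires theta >= 1, got {theta}")
    else:
        raise ValueError(f"unknown copula family {family!r}; choose from {FAMILIES}")


@dataclass(frozen=True)
class CopulaSpec:
    """A fully resolved bivariate copula: family, Kendall tau and parameter.

    ``rotated_270`` is true exactly when ``kendall_tau < 0`` and the family is
    Clayton or Joe; in that case ``theta`` is the parameter of the base
    (positive-dependence) copula at ``|kendall_tau|`` and the rotation
    ``rC(u, v) = u - C(u, 1 - v)`` is applied at the CDF/sampling layer.
    """

    family: str
    kendall_tau: float
    rotated_270: bool = False
    theta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        if not -1.0 < self.kendall_tau < 1.0:
            raise ValueError("kendall_tau must lie in (-1, 1)")
        expect_rot = self.kendall_tau < 0 and self.family in ("clayton", "joe")
        if self.rotated_270 != expect_rot:
            raise ValueError(
                "rotated_270 must be set iff kendall_tau < 0 and the family is clayton or joe"
            )
        if self.theta is None:
            object.__setattr__(self, "theta", tau_to_theta(self.family, self.kendall_tau))
        _validate_theta(self.family, self.theta)
        # round-trip consistency between tau and theta
        base_tau = abs(self.kendall_tau) if self.rotated_270 else self.kendall_tau
        if abs(_base_tau_of(self.family, self.theta) - base_tau) > 1e-6:
            raise ValueError("theta and kendall_tau are inconsistent")

    @classmethod
    def from_tau(cls, family: str, kendall_tau: float) -> "CopulaSpec":
        rotated = kendall_tau < 0 and family in ("clayton", "joe")
        return cls(family=family, kendall_tau=kendall_tau, rotated_270=rotated)

    @property
    def independent(self) -> bool:
        return self.kendall_tau == 0.0


# ---------------------------------------------------------------------------
# Kendall tau <-> parameter
# ---------------------------------------------------------------------------

def _debye1(theta: float) -> float:
    """First Debye function D1(theta) = (1/theta) int_0^theta t/(e^t - 1) dt."""
    val, _ = integrate.quad(lambda t: t / math.expm1(t) if t != 0 else 1.0, 0.0, theta)
    return val / theta


def _frank_tau(theta: float) -> float:
    if theta == 0.0:
        return 0.0
    return 1.0 - 4.0 / theta * (1.0 - _debye1(theta))


def _joe_tau(theta: float) -> float:
    if theta == 1.0:
        return 0.0

    # tau = 1 + 4 int_0^1 phi(t)/phi'(t) dt with generator phi(t) = -log(1-(1-t)^theta),
    # i.e. integrand log(a) * a * (1-t)^(1-theta) / theta with a = 1-(1-t)^theta,
    # evaluated in log space to survive large theta
    def integrand(t):
        t = np.asarray(t, dtype=float)
        l1t = np.log1p(-t)
        ea = theta * l1t                       # log (1-t)^theta
        with np.errstate(divide="ignore", invalid="ignore"):
            log_a = np.log1p(-np.exp(ea))      # log a, 0 when (1-t)^theta underflows
            # log(-log a): series -log a ~ (1-t)^theta when a ~ 1
            log_neg_log_a = np.where(ea < -36.0, ea, np.log(-log_a))
            out = -np.exp(log_neg_log_a + log_a + (1.0 - theta) * l1t
                          - math.log(theta))
        return np.where(t >= 1.0, -0.0, np.where(t <= 0.0, 0.0, out))

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return 1.0 + 4.0 * val


def _base_tau_of(family: str, theta: float) -> float:
    """Kendall tau of the unrotated family at parameter theta (closed/1-D forms)."""
    if family == "normal":
        return 2.0 / math.pi * math.asin(theta)
    if family == "clayton":
        return theta / (theta + 2.0)
    if family == "frank":
        return _frank_tau(theta)
    return _joe_tau(theta)


def tau_to_theta(family: str, kendall_tau: float) -> float:
    """Resolve the dependence parameter giving the requested Kendall tau.

    For Clayton/Joe with negative tau the returned theta is that of the base
    copula at ``|tau|`` (the 270-degree rotation supplies the sign).
    """
    if not -1.0 < kendall_tau < 1.0:
        raise ValueError("kendall_tau must lie in (-1, 1)")
    tau = kendall_tau
    if family in ("clayton", "joe"):
        tau = abs(tau)
    if family == "normal":
        return math.sin(math.pi * tau / 2.0)
    if tau == 0.0:
        # independence limits
        return {"frank": 0.0, "clayton": 0.0, "joe": 1.0}[family]
    if family == "clayton":
        return 2.0 * tau / (1.0 - tau)
    if family == "frank":
        lo, hi = (-500.0, -1e-10) if tau < 0 else (1e-10, 500.0)
        return optimize.brentq(lambda th: _frank_tau(th) - tau, lo, hi, xtol=_INV_TOL)
    if family == "joe":
        hi = 2.0
        while _joe_tau(hi) < tau and hi < 1e6:
            hi *= 2.0
        return optimize.brentq(lambda th: _joe_tau(th) - tau, 1.0 + 1e-12, hi,
                               xtol=_INV_TOL)
    raise ValueError(f"unknown copula family {family!r}")


def kendall_tau_of(spec: CopulaSpec, method: str = "closed", n_grid: int = 400) -> float:
    """Kendall's tau of a copula spec.

    ``method='closed'`` uses the family closed or one-dimensional integral
    forms; ``method='integral'`` evaluates tau = 4 E[C(U,V)] - 1 by tensor
    Gauss-Legendre quadrature of C(u,v) c(u,v) over the unit square and serves
    as an independent numerical check of the closed forms.
    """
    if spec.independent:
        return 0.0
    if method == "closed":
        base = _base_tau_of(spec.family, spec.theta)
        return -base if spec.rotated_270 else base
    if method != "integral":
        raise ValueError("method must be 'closed' or 'integral'")
    x, w = np.polynomial.legendre.leggauss(n_grid)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    U, V = np.meshgrid(u, u, indexing="ij")
    c = np.exp(copula_logpdf(spec, U, V))
    C = copula_cdf(spec, U, V)
    return float(4.0 * np.sum(np.outer(wu, wu) * C * c) - 1.0)


# ---------------------------------------------------------------------------
# CDF / density
# ---------------------------------------------------------------------------

def _base_cdf(family: str, theta: float, u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "normal":
        if theta == 0.0:
            return u * v
        x = stats.norm.ppf(np.clip(u, _EPS, 1 - _EPS))
        y = stats.norm.ppf(np.clip(v, _EPS, 1 - _EPS))
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, theta], [theta, 1.0]])
        out = np.asarray(mvn.cdf(pts), dtype=float)
        # restore exact boundary values clipped away above
        out = np.where(u <= 0, 0.0, np.where(v <= 0, 0.0, out))
        out = np.where(u >= 1, np.minimum(v, 1.0) * np.ones_like(out), out)
        out = np.where(v >= 1, np.minimum(u, 1.0) * np.ones_like(out), out)
        return out
    if family == "frank":
        if theta == 0.0:
            return u * v
        num = np.expm1(-theta * u) * np.expm1(-theta * v)
        return -1.0 / theta * np.log1p(num / np.expm1(-theta))
    if family == "clayton":
        if theta == 0.0:
            return u * v
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            s = u ** (-theta) + v ** (-theta) - 1.0
            out = np.where(s > 0, s, np.inf) ** (-1.0 / theta)
        out = np.where((u <= 0) | (v <= 0), 0.0, out)
        if theta < 0:
            out = np.where(s <= 0, 0.0, out)
        return np.maximum(out, 0.0)
    # joe
    if theta == 1.0:
        return u * v
    a = (1.0 - u) ** theta
    b = (1.0 - v) ** theta
    return 1.0 - (a + b - a * b) ** (1.0 / theta)


def copula_cdf(spec: CopulaSpec, u, v):
    """C(u, v), applying the 270-degree rotation when the spec requires it."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
        raise ValueError("arguments must lie in the closed unit square")
    if spec.independent:
        return u * v
    if spec.rotated_270:
        return u - _base_cdf(spec.family, spec.theta, u, 1.0 - v)
    return _base_cdf(spec.family, spec.theta, u, v)


def _base_logpdf(family: str, theta: float, u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "normal":
        rho = theta
        if rho == 0.0:
            return np.zeros(np.broadcast(u, v).shape)
        x = stats.norm.ppf(u)
        y = stats.norm.ppf(v)
        r2 = 1.0 - rho * rho
        return (-0.5 * math.log(r2)
                - (rho * rho * (x * x + y * y) - 2.0 * rho * x * y) / (2.0 * r2))
    if family == "frank":
        if theta == 0.0:
            return np.zeros(np.broadcast(u, v).shape)
        em = -np.expm1(-theta)  # 1 - e^-theta; theta * em > 0 for any theta != 0
        den = em - (-np.expm1(-theta * u)) * (-np.expm1(-theta * v))
        return np.log(theta * em) - theta * (u + v) - 2.0 * np.log(np.abs(den))
    if family == "clayton":
        if theta == 0.0:
            return np.zeros(np.broadcast(u, v).shape)
        lu = np.log(u)
        lv = np.log(v)
        s = np.exp(-theta * lu) + np.exp(-theta * lv) - 1.0
        return (np.log1p(theta) - (theta + 1.0) * (lu + lv)
                + (-2.0 - 1.0 / theta) * np.log(s))
    # joe
    if theta == 1.0:
        return np.zeros(np.broadcast(u, v).shape)
    l1u = np.log1p(-u)
    l1v = np.log1p(-v)
    a = np.exp(theta * l1u)
    b = np.exp(theta * l1v)
    A = a + b - a * b
    return ((1.0 / theta - 2.0) * np.log(A) + (theta - 1.0) * (l1u + l1v)
            + np.log(theta - 1.0 + A))


def copula_logpdf(spec: CopulaSpec, u, v):
    """log copula density; rotation maps (u, v) -> (u, 1 - v)."""
    if spec.rotated_270:
        return _base_logpdf(spec.family, spec.theta, np.asarray(u, float),
                            1.0 - np.asarray(v, float))
    return _base_logpdf(spec.family, spec.theta, u, v)


# ---------------------------------------------------------------------------
# Conditional distribution and sampling
# ---------------------------------------------------------------------------

def _base_conditional_cdf(family: str, theta: float, u, v):
    """h(v | u) = dC(u, v)/du for the unrotated family."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if family == "normal":
        rho = theta
        x = stats.norm.ppf(u)
        y = stats.norm.ppf(v)
        return stats.norm.cdf((y - rho * x) / math.sqrt(1.0 - rho * rho))
    if family == "frank":
        a = np.exp(-theta * u)
        b = np.expm1(-theta * v)
        D = np.expm1(-theta)
        return a * b / (D + np.expm1(-theta * u) * b)
    if family == "clayton":
        with np.errstate(over="ignore"):
            s = u ** (-theta) + v ** (-theta) - 1.0
        return u ** (-theta - 1.0) * np.where(s > 0, s, np.inf) ** (-1.0 / theta - 1.0)
    # joe
    a = (1.0 - u) ** theta
    b = (1.0 - v) ** theta
    A = a + b - a * b
    return A ** (1.0 / theta - 1.0) * (1.0 - u) ** (theta - 1.0) * (1.0 - b)


def conditional_cdf(spec: CopulaSpec, u, v):
    """P(V <= v | U = u) under the spec (rotation included)."""
    if spec.independent:
        return np.broadcast_to(np.asarray(v, float), np.broadcast(u, v).shape).copy()
    if spec.rotated_270:
        return 1.0 - _base_conditional_cdf(spec.family, spec.theta, u, 1.0 - np.asarray(v, float))
    return _base_conditional_cdf(spec.family, spec.theta, u, v)


def _conditional_quantile(family: str, theta: float, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve h(v | u) = w for v, vectorised. Closed forms where available,
    bracketed bisection on [eps, 1-eps] otherwise (Joe)."""
    if family == "normal":
        rho = theta
        x = stats.norm.ppf(u)
        return stats.norm.cdf(rho * x + math.sqrt(1.0 - rho * rho) * stats.norm.ppf(w))
    if family == "frank":
        a = np.exp(-theta * u)
        # e^{-theta v} - 1 = w D / (a (1 - w) + w), D = e^{-theta} - 1
        D = math.expm1(-theta)
        b = w * D / (a * (1.0 - w) + w)
        return np.clip(-np.log1p(b) / theta, _EPS, 1.0 - _EPS)
    if family == "clayton" and theta > 0:
        t = np.exp(-theta / (1.0 + theta) * np.log(w)) - 1.0  # w^{-theta/(1+theta)} - 1
        return np.clip((t * u ** (-theta) + 1.0) ** (-1.0 / theta), _EPS, 1.0 - _EPS)
    # generic monotone bisection (joe, and clayton with theta < 0)
    lo = np.full_like(u, _EPS)
    hi = np.full_like(u, 1.0 - _EPS)
    for _ in range(64):  # 2^-64 < 1e-10 interval width
        mid = 0.5 * (lo + hi)
        too_low = _base_conditional_cdf(family, theta, u, mid) < w
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def sample_pairs(spec: CopulaSpec, n: int, rng) -> np.ndarray:
    """Draw ``n`` pairs from the copula by conditional inversion.

    Returns an (n, 2) array with exactly uniform margins.  ``rng`` is a
    ``numpy.random.Generator`` (or a seed accepted by ``default_rng``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    u = rng.uniform(_EPS, 1.0 - _EPS, size=n)
    w = rng.uniform(_EPS, 1.0 - _EPS, size=n)
    if spec.independent:
        v = w
    else:
        v = _conditional_quantile(spec.family, spec.theta, u, w)
        if spec.rotated_270:
            v = 1.0 - v
    return np.column_stack([u, v])


def gaussian_margins(pairs: np.ndarray) -> np.ndarray:
    """Map uniform pairs to standard-normal margins via Phi^{-1} componentwise."""
    pairs = np.asarray(pairs, dtype=float)
    if np.any(pairs <= 0.0) or np.any(pairs >= 1.0):
        raise ValueError("coordinates must lie strictly inside (0, 1)")
    return stats.norm.ppf(pairs)


# ---------------------------------------------------------------------------
# Derived dependence summaries
# ---------------------------------------------------------------------------

def pearson_from_copula(spec: CopulaSpec, n_grid: int = 512) -> float:
    """Pearson correlation of (Phi^{-1}(U), Phi^{-1}(V)) for (U, V) ~ C.

    Computed as E[XY] = iint x y c(Phi(x), Phi(y)) phi(x) phi(y) dx dy by
    tensor Gauss-Legendre quadrature on [-8, 8]^2 (the Gaussian-space form
    resolves the corner mass of tail-dependent families); the normal family
    short-circuits to rho = sin(pi tau / 2).
    """
    if spec.independent:
        return 0.0
    if spec.family == "normal":
        return math.sin(math.pi * spec.kendall_tau / 2.0)
    x, w = np.polynomial.legendre.leggauss(n_grid)
    L = 8.0
    x = x * L
    w = w * L
    ugrid = stats.norm.cdf(x)
    lphi = stats.norm.logpdf(x)
    UU, VV = np.meshgrid(ugrid, ugrid, indexing="ij")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        lw = _base_logpdf(spec.family, spec.theta, UU, VV) + lphi[:, None] + lphi[None, :]
        integrand = np.outer(x, x) * np.exp(lw)
    integrand = np.nan_to_num(integrand, nan=0.0, posinf=0.0, neginf=0.0)
    val = float(np.sum(np.outer(w, w) * integrand))
    return -val if spec.rotated_270 else val


def tail_dependence(spec: CopulaSpec) -> tuple[float, float]:
    """(lambda_L, lambda_U) tail-dependence coefficients.

    Clayton has lower tail dependence 2^{-1/theta}; Joe has upper tail
    dependence 2 - 2^{1/theta}; Frank and normal have none.  Rotated specs
    report (0, 0): their dependence sits in the off-diagonal corners, which
    the diagonal coefficients do not measure.
    """
    if spec.rotated_270 or spec.independent:
        return (0.0, 0.0)
    if spec.family == "clayton" and spec.theta > 0:
        return (2.0 ** (-1.0 / spec.theta), 0.0)
    if spec.family == "joe":
        return (0.0, 2.0 - 2.0 ** (1.0 / spec.theta))
    return (0.0, 0.0)
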