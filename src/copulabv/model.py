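"""Bivariate animal model: mixed-model equations, BLUP and REML.

The model for traits j = 1, 2 is ``y_j = X_j beta_j + a_j + e_j`` with
additive-genetic effects ``(a_1, a_2) ~ N(0, Sigma_a (x) A)`` (A the pedigree
numerator relationship matrix) and residuals with covariance ``Sigma_e`` per
animal, independent across animals.  Records with a missing trait contribute
only the observed trait's residual precision (the missing trait is integrated
out, not imputed).  Breeding values and fixed effects solve Henderson's
mixed-model equations; variance components maximise the restricted
likelihood.

REML is computed from the sparse MME factorisation:

    -2 l_R = log|R| + log|G| + log|C| + y' P y  (+ const),

with ``y'Py = y'R^{-1}y - r' s`` for MME solution s and right-hand side r,
``log|G| = n log|Sigma_a| + 2 log|A|`` and ``log|A|`` available in closed
form from the pedigree.  The coefficient matrix is assembled as a scalar
linear combination of parameter-free sparse blocks, so each likelihood
evaluation costs one sparse LU factorisation.  The restricted likelihood is
maximised by quasi-Newton iteration (L-BFGS-B) on the Cholesky factors of
``Sigma_a`` and ``Sigma_e``, which keeps every iterate positive definite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.sparse.linalg import splu

from .pedigree import Pedigree
from .sparse_chol import PatternLDL

__all__ = [
    "VarianceComponents",
    "MMESystem",
    "BivariateAnimalModel",
    "BivariateAnimalModelResults",
    "heritability",
    "genetic_gain",
]

_SPLU_OPTS = dict(permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                  options=dict(SymmetricMode=True))


@dataclass(frozen=True)
class VarianceComponents:
    """The six (co)variance parameters of the bivariate animal model."""

    sigma2_a1: float
    sigma_a12: float
    sigma2_a2: float
    sigma2_e1: float
    sigma_e12: float
    sigma2_e2: float

    def __post_init__(self):
        for M, name in ((self.Sigma_a, "genetic"), (self.Sigma_e, "residual")):
            if np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError(f"{name} covariance matrix is not positive definite")

    @property
    def Sigma_a(self) -> np.ndarray:
        return np.array([[self.sigma2_a1, self.sigma_a12],
                         [self.sigma_a12, self.sigma2_a2]])

    @property
    def Sigma_e(self) -> np.ndarray:
        return np.array([[self.sigma2_e1, self.sigma_e12],
                         [self.sigma_e12, self.sigma2_e2]])

    @classmethod
    def from_matrices(cls, Sigma_a, Sigma_e) -> "VarianceComponents":
        Sa = np.asarray(Sigma_a, float)
        Se = np.asarray(Sigma_e, float)
        return cls(Sa[0, 0], Sa[0, 1], Sa[1, 1], Se[0, 0], Se[0, 1], Se[1, 1])

    @property
    def heritability(self) -> tuple[float, float]:
        return heritability(self)

    @property
    def genetic_correlation(self) -> float:
        return self.sigma_a12 / math.sqrt(self.sigma2_a1 * self.sigma2_a2)

    @property
    def residual_correlation(self) -> float:
        return self.sigma_e12 / math.sqrt(self.sigma2_e1 * self.sigma2_e2)

    # -- unconstrained parameter vector (Cholesky of each 2x2 matrix) ------

    def to_params(self, fix_covariances: bool = False) -> np.ndarray:
        out = []
        for M in (self.Sigma_a, self.Sigma_e):
            L = np.linalg.cholesky(M)
            if fix_covariances:
                out += [math.log(L[0, 0]), math.log(L[1, 1])]
            else:
                out += [math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])]
        return np.array(out)

    @classmethod
    def from_params(cls, z: np.ndarray, fix_covariances: bool = False
                    ) -> "VarianceComponents":
        z = np.asarray(z, float)
        mats = []
        if fix_covariances:
            for l11, l22 in (z[:2], z[2:]):
                mats.append(np.diag([math.exp(2 * l11), math.exp(2 * l22)]))
        else:
            for l11, l21, l22 in (z[:3], z[3:]):
                L = np.array([[math.exp(l11), 0.0], [l21, math.exp(l22)]])
                mats.append(L @ L.T)
        return cls.from_matrices(*mats)


def heritability(vc: VarianceComponents) -> tuple[float, float]:
    """Narrow-sense heritability per trait: sigma2_a / (sigma2_a + sigma2_e)."""
    return (vc.sigma2_a1 / (vc.sigma2_a1 + vc.sigma2_e1),
            vc.sigma2_a2 / (vc.sigma2_a2 + vc.sigma2_e2))


@dataclass
class MMESystem:
    """Henderson mixed-model equations: C s = r.

    Layout of s: [beta_1 (p), a_1 (n), beta_2 (p), a_2 (n)].
    """

    coef: sparse.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    n_animals: int

    def solve(self) -> np.ndarray:
        return splu(self.coef, **_SPLU_OPTS).solve(self.rhs)


class BivariateAnimalModel:
    """Two-trait animal model on a pedigree, ready for BLUP and REML.

    Parameters
    ----------
    phenotypes : DataFrame with columns ``id``, ``y1``, ``y2`` (NaN where a
        trait is unrecorded) and the categorical fixed-effect columns.
    pedigree : :class:`~copulabv.pedigree.Pedigree` covering ids 1..n in
        birth order; every phenotyped animal must appear.
    factors : names of the fixed-effect columns (reference-level coding with
        an intercept is applied per trait).
    """

    def __init__(self, phenotypes: pd.DataFrame, pedigree: Pedigree,
                 factors: tuple[str, ...] = ("f1", "f2", "f3")):
        self.pedigree = pedigree
        n = pedigree.n
        ph = phenotypes.set_index("id").reindex(np.arange(1, n + 1))
        y1 = ph["y1"].to_numpy(dtype=float)
        y2 = ph["y2"].to_numpy(dtype=float)
        self.y = np.column_stack([y1, y2])
        self.factors = tuple(factors)

        # fixed-effect design: intercept + dummy columns dropping level 0
        cols = [np.ones(n)]
        names = ["intercept"]
        for f in factors:
            lev = ph[f].to_numpy()
            lev = np.where(pd.isna(lev), 0, lev).astype(int)
            for l in np.unique(lev):
                if l == np.min(lev):
                    continue
                cols.append((lev == l).astype(float))
                names.append(f"{f}[{l}]")
        X = np.column_stack(cols)
        self.X = X
        self.p = X.shape[1]
        self.fe_names = names
        self.n = n

        obs1 = np.isfinite(y1)
        obs2 = np.isfinite(y2)
        self._mask_b = obs1 & obs2
        self._mask_o1 = obs1 & ~obs2
        self._mask_o2 = obs2 & ~obs1
        self.n_both = int(self._mask_b.sum())
        self.n_only1 = int(self._mask_o1.sum())
        self.n_only2 = int(self._mask_o2.sum())
        if self.n_both + self.n_only1 + self.n_only2 == 0:
            raise ValueError("no phenotyped animals")

        W = sparse.hstack([sparse.csr_matrix(X), sparse.eye(n, format="csr")],
                          format="csr")
        self.q = self.p + n
        ainv, self.logdet_A = pedigree.a_inverse()
        pad = sparse.block_diag(
            [sparse.csr_matrix((self.p, self.p)), ainv], format="csc")

        def cross(mask):
            Wm = W[np.nonzero(mask)[0]]
            return (Wm.T @ Wm).tocsc()

        Mb = cross(self._mask_b)
        Mo1 = cross(self._mask_o1)
        Mo2 = cross(self._mask_o2)
        Z = sparse.csc_matrix((self.q, self.q))

        def blocks(m00=None, m01=None, m11=None):
            return sparse.bmat([[m00 if m00 is not None else Z,
                                 m01 if m01 is not None else Z],
                                [(m01.T if m01 is not None else Z),
                                 m11 if m11 is not None else Z]],
                               format="csc")

        comps = {
            "b11": blocks(m00=Mb), "b12": blocks(m01=Mb), "b22": blocks(m11=Mb),
            "o1": blocks(m00=Mo1), "o2": blocks(m11=Mo2),
            "g11": blocks(m00=pad), "g12": blocks(m01=pad), "g22": blocks(m11=pad),
        }
        patt = None
        for M in comps.values():
            M.sort_indices()
            ones = sparse.csc_matrix(
                (np.ones_like(M.data), M.indices, M.indptr), shape=M.shape)
            patt = ones if patt is None else patt + ones
        pattern = sparse.csc_matrix(
            (np.zeros_like(patt.data), patt.indices, patt.indptr), shape=patt.shape)
        pattern.sort_indices()
        self._pattern = pattern
        self._comp_data = {}
        for k, M in comps.items():
            self._comp_data[k] = (self._map_into(pattern, M), M.data.copy())
        neutral = VarianceComponents(0.3, 0.0, 0.3, 0.7, 0.0, 0.7)
        self._ldl = PatternLDL(pattern, self._assemble_data(neutral))

        # parameter-free RHS pieces
        yb1 = np.where(self._mask_b, y1, 0.0)
        yb2 = np.where(self._mask_b, y2, 0.0)
        yo1 = np.where(self._mask_o1, y1, 0.0)
        yo2 = np.where(self._mask_o2, y2, 0.0)
        self._v = {
            "b1": W.T @ yb1, "b2": W.T @ yb2, "o1": W.T @ yo1, "o2": W.T @ yo2,
        }
        self._yy = {
            "b11": float(yb1 @ yb1), "b12": float(yb1 @ yb2),
            "b22": float(yb2 @ yb2),
            "o11": float(yo1 @ yo1), "o22": float(yo2 @ yo2),
        }

        # Canonical-transformation fast path.  When every record has both
        # traits, the generalised eigendecomposition Sigma_a v = lambda
        # Sigma_e v (T' Sigma_e T = I, T' Sigma_a T = diag(lambda))
        # decouples the model into two independent univariate animal models
        # on the transformed traits y* = T'y, with unit residual variance and
        # genetic variance lambda_j.  Each likelihood evaluation then costs
        # two half-order factorisations instead of one bivariate one:
        #   -2 l_R = sum_j [ n log lambda_j + log|A| + log|C_j| + y*_j P y*_j ]
        #            + (n_rec - p) log|Sigma_e|.
        self._complete = self.n_only1 == 0 and self.n_only2 == 0
        if self._complete:
            rows = np.nonzero(self._mask_b)[0]
            Xo = X[rows]
            Zsel = sparse.csr_matrix(
                (np.ones(rows.size), (np.arange(rows.size), rows)),
                shape=(rows.size, n))
            Wu = sparse.hstack([sparse.csr_matrix(Xo), Zsel], format="csr")
            Cu = (Wu.T @ Wu).tocsc()
            pad_u = sparse.block_diag(
                [sparse.csr_matrix((self.p, self.p)), ainv], format="csc")
            Cu.sort_indices()
            pad_u.sort_indices()
            ones = lambda M: sparse.csc_matrix(  # noqa: E731
                (np.ones_like(M.data), M.indices, M.indptr), shape=M.shape)
            up = ones(Cu) + ones(pad_u)
            upat = sparse.csc_matrix(
                (np.zeros_like(up.data), up.indices, up.indptr), shape=up.shape)
            upat.sort_indices()
            self._uni = {
                "pattern": upat,
                "data": (self._map_into(upat, Cu), Cu.data.copy()),
                "pad": (self._map_into(upat, pad_u), pad_u.data.copy()),
                "Xo": Xo, "rows": rows,
            }
            useed = np.zeros_like(upat.data)
            useed[self._uni["data"][0]] += self._uni["data"][1]
            useed[self._uni["pad"][0]] += self._uni["pad"][1]
            self._uni["ldl"] = PatternLDL(upat, useed)

    @staticmethod
    def _map_into(U: sparse.csc_matrix, M: sparse.csc_matrix) -> np.ndarray:
        """Positions of M's entries inside U.data (M's pattern is a subset)."""
        idx = np.empty(M.nnz, dtype=np.int64)
        for c in range(M.shape[1]):
            m0, m1 = M.indptr[c], M.indptr[c + 1]
            if m0 == m1:
                continue
            u0, u1 = U.indptr[c], U.indptr[c + 1]
            idx[m0:m1] = u0 + np.searchsorted(U.indices[u0:u1], M.indices[m0:m1])
        return idx

    # -- assembly ---------------------------------------------------------

    def _coefficients(self, vc: VarianceComponents) -> dict[str, float]:
        e = np.linalg.inv(vc.Sigma_e)
        g = np.linalg.inv(vc.Sigma_a)
        return {
            "b11": e[0, 0], "b12": e[0, 1], "b22": e[1, 1],
            "o1": 1.0 / vc.sigma2_e1, "o2": 1.0 / vc.sigma2_e2,
            "g11": g[0, 0], "g12": g[0, 1], "g22": g[1, 1],
        }

    def _assemble_data(self, vc: VarianceComponents) -> np.ndarray:
        coefs = self._coefficients(vc)
        data = np.zeros_like(self._pattern.data)
        for k, (idx, vals) in self._comp_data.items():
            data[idx] += coefs[k] * vals  # idx unique within each component
        return data

    def _assemble_rhs(self, vc: VarianceComponents) -> np.ndarray:
        e = np.linalg.inv(vc.Sigma_e)
        v = self._v
        r1 = e[0, 0] * v["b1"] + e[0, 1] * v["b2"] + v["o1"] / vc.sigma2_e1
        r2 = e[0, 1] * v["b1"] + e[1, 1] * v["b2"] + v["o2"] / vc.sigma2_e2
        return np.concatenate([r1, r2])

    def build_mme(self, vc: VarianceComponents) -> MMESystem:
        data = self._assemble_data(vc)
        C = sparse.csc_matrix((data, self._pattern.indices, self._pattern.indptr),
                              shape=self._pattern.shape)
        return MMESystem(coef=C, rhs=self._assemble_rhs(vc),
                         n_fixed=self.p, n_animals=self.n)

    def _y_rinv_y(self, vc: VarianceComponents) -> float:
        e = np.linalg.inv(vc.Sigma_e)
        yy = self._yy
        return (e[0, 0] * yy["b11"] + 2.0 * e[0, 1] * yy["b12"]
                + e[1, 1] * yy["b22"]
                + yy["o11"] / vc.sigma2_e1 + yy["o22"] / vc.sigma2_e2)

    # -- likelihood, BLUP, REML -------------------------------------------

    def loglike(self, vc: VarianceComponents) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        return -0.5 * self._neg2_loglike(vc)

    def _neg2_loglike_canonical(self, vc: VarianceComponents) -> float:
        lam, T = linalg.eigh(vc.Sigma_a, vc.Sigma_e)
        uni = self._uni
        ystar = self.y[uni["rows"]] @ T
        _, logdet_Se = np.linalg.slogdet(vc.Sigma_e)
        total = (len(uni["rows"]) - self.p) * logdet_Se
        pattern = uni["pattern"]
        idx0, vals0 = uni["data"]
        idxp, valsp = uni["pad"]
        for j in range(2):
            data = np.zeros_like(pattern.data)
            data[idx0] += vals0
            data[idxp] += valsp / lam[j]
            fac = uni["ldl"].factor(data)
            yj = ystar[:, j]
            rhs = np.zeros(self.p + self.n)
            rhs[:self.p] = uni["Xo"].T @ yj
            rhs[self.p + uni["rows"]] = yj
            sol = fac.solve(rhs)
            total += (self.n * math.log(lam[j]) + self.logdet_A + fac.logdet
                      + float(yj @ yj) - float(rhs @ sol))
        return total

    def _neg2_loglike(self, vc: VarianceComponents,
                      return_solution: bool = False):
        if self._complete and not return_solution:
            return self._neg2_loglike_canonical(vc)
        fac = self._ldl.factor(self._assemble_data(vc))
        rhs = self._assemble_rhs(vc)
        sol = fac.solve(rhs)
        logdet_C = fac.logdet
        _, logdet_Se = np.linalg.slogdet(vc.Sigma_e)
        _, logdet_Sa = np.linalg.slogdet(vc.Sigma_a)
        logdet_R = (self.n_both * logdet_Se
                    + self.n_only1 * math.log(vc.sigma2_e1)
                    + self.n_only2 * math.log(vc.sigma2_e2))
        logdet_G = self.n * logdet_Sa + 2.0 * self.logdet_A
        ypy = self._y_rinv_y(vc) - float(rhs @ sol)
        val = logdet_R + logdet_G + logdet_C + ypy
        if return_solution:
            return val, sol
        return val

    def blup(self, vc: VarianceComponents) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Solve the MME at the given components.

        Returns ``(fixed_effects, ebv)``: the fixed-effect solutions per trait
        and a per-animal table of estimated breeding values for all pedigree
        members (phenotyped or not).
        """
        sol = self._ldl.factor(self._assemble_data(vc)).solve(
            self._assemble_rhs(vc))
        q, p, n = self.q, self.p, self.n
        fe = pd.DataFrame({"effect": self.fe_names,
                           "trait1": sol[:p], "trait2": sol[q:q + p]})
        ebv = pd.DataFrame({"id": np.arange(1, n + 1),
                            "generation": self.pedigree.generation,
                            "ebv1": sol[p:q], "ebv2": sol[q + p:]})
        return fe, ebv

    def fit(self, start: VarianceComponents | None = None,
            fix_covariances: bool = False, maxiter: int = 200,
            polish: bool = False) -> "BivariateAnimalModelResults":
        """Estimate the variance components by REML.

        ``start`` defaults to a neutral point (genetic variance 0.3, residual
        0.7, zero covariances).  ``polish=True`` appends a derivative-free
        Nelder-Mead refinement, useful on small problems when estimates are
        compared against high-precision oracles.
        """
        if start is None:
            start = VarianceComponents(0.3, 0.0, 0.3, 0.7, 0.0, 0.7)
        z0 = start.to_params(fix_covariances)
        path: list[tuple[np.ndarray, float]] = []

        cache: dict[bytes, float] = {}

        def objective(z):
            key = np.asarray(z).tobytes()
            if key in cache:
                return cache[key]
            try:
                vc = VarianceComponents.from_params(z, fix_covariances)
                val = self._neg2_loglike(vc)
            except (ValueError, FloatingPointError, RuntimeError):
                val = 1e12
            cache[key] = val
            return val

        f0 = objective(z0)
        path.append((z0.copy(), f0))

        def callback(z):
            path.append((z.copy(), objective(z)))

        res = optimize.minimize(
            objective, z0, method="L-BFGS-B", callback=callback,
            options=dict(maxiter=maxiter, ftol=1e-11, gtol=1e-6, eps=1e-6))
        z, fval = res.x, float(res.fun)
        if polish:
            res2 = optimize.minimize(
                objective, z, method="Nelder-Mead",
                options=dict(xatol=1e-9, fatol=1e-10, maxiter=4000))
            if res2.fun < fval:
                z, fval = res2.x, float(res2.fun)
            path.append((z.copy(), fval))

        if len(path) >= 2:
            (z_prev, f_prev), (z_last, f_last) = path[-2], path[-1]
            small_step = (abs(f_prev - f_last) <= 1e-8 * max(1.0, abs(f_last))
                          and np.max(np.abs(z_prev - z_last)) < 1e-6)
        else:
            small_step = False
        converged = bool(res.success or small_step)
        vc = VarianceComponents.from_params(z, fix_covariances)
        return BivariateAnimalModelResults(
            model=self, params=vc, loglike=-0.5 * fval, converged=converged,
            n_iter=int(res.nit), message=str(res.message),
            loglike_path=[-0.5 * f for _, f in path])


@dataclass
class BivariateAnimalModelResults:
    """REML estimates with BLUP solutions computed at the estimates."""

    model: BivariateAnimalModel
    params: VarianceComponents
    loglike: float
    converged: bool
    n_iter: int
    message: str
    loglike_path: list = field(default_factory=list)
    _blup: tuple | None = field(default=None, repr=False)

    def _ensure_blup(self):
        if self._blup is None:
            self._blup = self.model.blup(self.params)
        return self._blup

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return self._ensure_blup()[0]

    @property
    def ebv(self) -> pd.DataFrame:
        return self._ensure_blup()[1]

    @property
    def heritability(self) -> tuple[float, float]:
        return self.params.heritability

    @property
    def genetic_correlation(self) -> float:
        return self.params.genetic_correlation

    @property
    def residual_correlation(self) -> float:
        return self.params.residual_correlation

    def genetic_gain(self, generation: int, sigma2_a_true) -> tuple[float, float]:
        return genetic_gain(self.ebv, generation, sigma2_a_true)

    def summary(self) -> str:
        vc = self.params
        h1, h2 = self.heritability
        lines = [
            "Bivariate animal model (REML)",
            "=" * 46,
            f"animals: {self.model.n}   records: "
            f"{self.model.n_both} complete, "
            f"{self.model.n_only1 + self.model.n_only2} single-trait",
            f"restricted log-likelihood: {self.loglike:.4f}"
            f"   converged: {self.converged} ({self.n_iter} iterations)",
            "-" * 46,
            f"{'component':<22}{'estimate':>12}",
            f"{'genetic var trait 1':<22}{vc.sigma2_a1:>12.4f}",
            f"{'genetic covariance':<22}{vc.sigma_a12:>12.4f}",
            f"{'genetic var trait 2':<22}{vc.sigma2_a2:>12.4f}",
            f"{'residual var trait 1':<22}{vc.sigma2_e1:>12.4f}",
            f"{'residual covariance':<22}{vc.sigma_e12:>12.4f}",
            f"{'residual var trait 2':<22}{vc.sigma2_e2:>12.4f}",
            "-" * 46,
            f"heritability:        h2_1 = {h1:.3f}   h2_2 = {h2:.3f}",
            f"genetic correlation:  {self.genetic_correlation:+.3f}",
            f"residual correlation: {self.residual_correlation:+.3f}",
        ]
        return "\n".join(lines)


def genetic_gain(ebv: pd.DataFrame, generation: int, sigma2_a_true
                 ) -> tuple[float, float]:
    """Mean EBV of generation ``generation`` minus the founder mean, in units
    of the true genetic standard deviation, per trait."""
    s = np.sqrt(np.asarray(sigma2_a_true, dtype=float))
    g0 = ebv[ebv["generation"] == 0]
    gk = ebv[ebv["generation"] == generation]
    if len(gk) == 0 or len(g0) == 0:
        raise ValueError(f"no animals in generation {generation} or 0")
    d1 = gk["ebv1"].mean() - g0["ebv1"].mean()
    d2 = gk["ebv2"].mean() - g0["ebv2"].mean()
    return (float(d1 / s[0]), float(d2 / s[1]))
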