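"""Breeding-scheme simulator.

Emulates a simplified two-trait pig scheme: 12 founder sires and 204 founder
dams (17 dams per sire), discrete generations, fixed litter sizes with an
unbalanced sex ratio, additive-genetic effects from a bivariate Gaussian with
covariance Sigma (Mendelian sampling variance Sigma/2), and residuals with
standard-normal margins whose dependence follows a chosen copula.  Phenotypes
follow the bivariate animal model y_j = X beta_j + a_j + e_j with three
categorical fixed effects (3, 2 and 2 levels) per trait.

Two designs are supported:

* ``complete`` - 12 offspring per dam (2 M, 10 F), both traits recorded on
  everyone, everyone a selection candidate; 2448 animals per generation at
  full scale, 19,800 in total over eight generations.
* ``missing_trait2`` - 24 offspring per dam (4 M, 20 F), half of each sex
  missing the second trait (e.g. a trait measured after culling); only the
  animals with the missing record are selection candidates; 4896 animals per
  generation, 39,384 in total, 2448 candidates per generation.

A ``scale`` factor shrinks the number of sire families (dams per sire,
litter sizes and selection fractions are preserved) for desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copulas import CopulaSpec, gaussian_margins, sample_pairs
from .pedigree import UNKNOWN, Pedigree

__all__ = ["SchemeConfig", "Population", "simulate_founders", "mendelian_offspring"]

# fixed-effect values per level (same for both traits by default)
DEFAULT_EFFECTS = (
    np.array([0.0, 1.0, -1.0]),
    np.array([0.5, -0.5]),
    np.array([0.3, -0.3]),
)


@dataclass
class SchemeConfig:
    """Study conditions for one simulated population."""

    design: str = "complete"            # or "missing_trait2"
    sigma2_a: tuple[float, float] = (0.67, 0.67)
    tau_a: float = 0.4                  # Kendall tau of the (Gaussian) genetic effects
    residual_copula: CopulaSpec = field(
        default_factory=lambda: CopulaSpec.from_tau("normal", 0.4))
    sigma2_e: tuple[float, float] = (1.0, 1.0)
    scale: float = 1.0                  # fraction of the 12 sire families kept
    dams_per_sire: int = 17
    n_generations: int = 8
    n_random: int = 3                   # generations bred from randomly chosen parents
    effects: tuple[np.ndarray, ...] = DEFAULT_EFFECTS

    def __post_init__(self):
        if self.design not in ("complete", "missing_trait2"):
            raise ValueError("design must be 'complete' or 'missing_trait2'")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must lie in (0, 1]")
        if min(self.sigma2_a) < 0 or min(self.sigma2_e) <= 0:
            raise ValueError("variances must be positive")

    @property
    def n_sires(self) -> int:
        return max(2, round(12 * self.scale))

    @property
    def n_dams(self) -> int:
        return self.n_sires * self.dams_per_sire

    @property
    def litter_size(self) -> int:
        return 12 if self.design == "complete" else 24

    @property
    def males_per_litter(self) -> int:
        return 2 if self.design == "complete" else 4

    @property
    def rho_a(self) -> float:
        return math.sin(math.pi * self.tau_a / 2.0)

    @property
    def Sigma(self) -> np.ndarray:
        """Genetic covariance matrix implied by (sigma2_a, tau_a)."""
        s1, s2 = self.sigma2_a
        cov = self.rho_a * math.sqrt(s1 * s2)
        return np.array([[s1, cov], [cov, s2]])

    @property
    def Sigma_e(self) -> np.ndarray:
        """Residual covariance implied by the copula's Pearson correlation."""
        from .copulas import pearson_from_copula
        s1, s2 = self.sigma2_e
        cov = pearson_from_copula(self.residual_copula) * math.sqrt(s1 * s2)
        return np.array([[s1, cov], [cov, s2]])


def _cov_factor(Sigma: np.ndarray) -> np.ndarray:
    """Square-root factor L with L L' = Sigma, tolerant of PSD-singular input."""
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(Sigma)
        if np.any(w < -1e-12):
            raise ValueError("covariance matrix is not positive semi-definite")
        return v * np.sqrt(np.clip(w, 0.0, None))


def mendelian_offspring(a_sire: np.ndarray, a_dam: np.ndarray,
                        Sigma: np.ndarray, rng) -> np.ndarray:
    """Offspring breeding values: parent average plus N(0, Sigma/2) deviation."""
    a_sire = np.atleast_2d(a_sire)
    a_dam = np.atleast_2d(a_dam)
    L = _cov_factor(np.asarray(Sigma) / 2.0)
    m = rng.standard_normal((a_sire.shape[0], 2)) @ L.T
    return 0.5 * (a_sire + a_dam) + m


class Population:
    """Growing pedigree with genetic values, residuals and phenotypes.

    Rows are birth-ordered; the 1-based id of row i is i + 1.  ``y`` holds
    NaN where the second trait is missing.
    """

    def __init__(self, config: SchemeConfig):
        self.config = config
        n0 = 0
        self.sire = np.empty(n0, dtype=np.int64)
        self.dam = np.empty(n0, dtype=np.int64)
        self.sex = np.empty(n0, dtype="U1")
        self.generation = np.empty(n0, dtype=np.int64)
        self.candidate = np.empty(n0, dtype=bool)
        self.trait2_missing = np.empty(n0, dtype=bool)
        self.a = np.empty((n0, 2))
        self.eps = np.empty((n0, 2))
        self.levels = np.empty((n0, 3), dtype=np.int64)
        self.y = np.empty((n0, 2))

    # -- construction -----------------------------------------------------

    @classmethod
    def founders(cls, config: SchemeConfig, rng_gen, rng_struct, rng_res) -> "Population":
        """Unrelated founder generation: n_sires males + n_dams females,
        breeding values ~ N(0, Sigma), complete phenotypes."""
        pop = cls(config)
        n_m, n_f = config.n_sires, config.n_dams
        n = n_m + n_f
        pop.sire = np.full(n, UNKNOWN, dtype=np.int64)
        pop.dam = np.full(n, UNKNOWN, dtype=np.int64)
        pop.sex = np.array(["M"] * n_m + ["F"] * n_f)
        pop.generation = np.zeros(n, dtype=np.int64)
        pop.candidate = np.ones(n, dtype=bool)
        pop.trait2_missing = np.zeros(n, dtype=bool)
        L = _cov_factor(config.Sigma)
        pop.a = rng_gen.standard_normal((n, 2)) @ L.T
        pop.eps = np.empty((n, 2))
        pop.levels = np.empty((n, 3), dtype=np.int64)
        pop.y = np.empty((n, 2))
        pop._assemble_phenotypes(np.arange(n), rng_struct, rng_res)
        return pop

    def add_generation(self, sire_rows: np.ndarray, dam_rows: np.ndarray,
                       rng_struct, rng_gen, rng_res) -> np.ndarray:
        """Mate the selected parents and append their offspring.

        Dams are assigned to sires at random subject to the no-sib-mating
        rule (a sire is never mated to a female sharing one of his parents);
        each dam produces one litter with the design's fixed sex split.
        Returns the row indices of the new generation.
        """
        cfg = self.config
        if len(sire_rows) != cfg.n_sires or len(dam_rows) != cfg.n_dams:
            raise ValueError("expected exactly n_sires sires and n_dams dams")
        assign = self._assign_matings(np.asarray(sire_rows), np.asarray(dam_rows),
                                      rng_struct)
        gen = self.generation.max() + 1

        lit = cfg.litter_size
        n_m = cfg.males_per_litter
        dams_flat = assign.reshape(-1)                     # n_dams, grouped by sire
        sires_flat = np.repeat(np.asarray(sire_rows), cfg.dams_per_sire)
        off_sire = np.repeat(sires_flat, lit)
        off_dam = np.repeat(dams_flat, lit)
        sex_pattern = np.array(["M"] * n_m + ["F"] * (lit - n_m))
        off_sex = np.tile(sex_pattern, len(dams_flat))
        n_new = len(off_sire)

        if cfg.design == "missing_trait2":
            # half of each sex lacks the second trait and only they are candidates
            miss_pattern = np.zeros(lit, dtype=bool)
            miss_pattern[: n_m // 2] = True                       # 2 of 4 males
            miss_pattern[n_m: n_m + (lit - n_m) // 2] = True      # 10 of 20 females
            off_missing = np.tile(miss_pattern, len(dams_flat))
            off_candidate = off_missing.copy()
        else:
            off_missing = np.zeros(n_new, dtype=bool)
            off_candidate = np.ones(n_new, dtype=bool)

        a_off = mendelian_offspring(self.a[off_sire], self.a[off_dam],
                                    cfg.Sigma, rng_gen)

        start = len(self)
        self.sire = np.concatenate([self.sire, off_sire])
        self.dam = np.concatenate([self.dam, off_dam])
        self.sex = np.concatenate([self.sex, off_sex])
        self.generation = np.concatenate([self.generation,
                                          np.full(n_new, gen, dtype=np.int64)])
        self.candidate = np.concatenate([self.candidate, off_candidate])
        self.trait2_missing = np.concatenate([self.trait2_missing, off_missing])
        self.a = np.vstack([self.a, a_off])
        rows = np.arange(start, start + n_new)
        self.eps = np.vstack([self.eps, np.empty((n_new, 2))])
        self.levels = np.vstack([self.levels, np.empty((n_new, 3), dtype=np.int64)])
        self.y = np.vstack([self.y, np.empty((n_new, 2))])
        self._assemble_phenotypes(rows, rng_struct, rng_res)
        return rows

    def _assign_matings(self, sire_rows: np.ndarray, dam_rows: np.ndarray,
                        rng_struct, max_iter: int = 1000) -> np.ndarray:
        """Random dams-to-sires assignment avoiding shared-parent pairs.

        Starts from a random permutation and repairs conflicts by random
        swaps; raises after ``max_iter`` sweeps without success.
        """
        ns, dps = len(sire_rows), self.config.dams_per_sire
        perm = rng_struct.permutation(dam_rows)
        assign = perm.reshape(ns, dps)

        def conflicts(i, dams):
            s = sire_rows[i]
            bad = np.zeros(len(dams), dtype=bool)
            if self.sire[s] != UNKNOWN:
                bad |= self.sire[dams] == self.sire[s]
            if self.dam[s] != UNKNOWN:
                bad |= self.dam[dams] == self.dam[s]
            return bad

        for _ in range(max_iter):
            bad_pos = [(i, j) for i in range(ns)
                       for j in np.nonzero(conflicts(i, assign[i]))[0]]
            if not bad_pos:
                return assign
            for (i, j) in bad_pos:
                if not conflicts(i, assign[i, j:j + 1])[0]:
                    continue  # fixed by an earlier swap
                for _try in range(50):
                    i2 = int(rng_struct.integers(ns))
                    j2 = int(rng_struct.integers(dps))
                    if i2 == i:
                        continue
                    d1, d2 = assign[i, j], assign[i2, j2]
                    if (not conflicts(i, np.array([d2]))[0]
                            and not conflicts(i2, np.array([d1]))[0]):
                        assign[i, j], assign[i2, j2] = d2, d1
                        break
        raise RuntimeError("could not find a mating assignment avoiding sib matings")

    def _assemble_phenotypes(self, rows: np.ndarray, rng_struct, rng_res) -> None:
        """Draw fixed-effect levels and copula residuals, form phenotypes."""
        cfg = self.config
        n = len(rows)
        for f, eff in enumerate(cfg.effects):
            self.levels[rows, f] = rng_struct.integers(len(eff), size=n)
        pairs = sample_pairs(cfg.residual_copula, n, rng_res)
        eps = gaussian_margins(pairs)
        eps = eps * np.sqrt(np.asarray(cfg.sigma2_e))
        self.eps[rows] = eps
        fixed = np.zeros(n)
        for f, eff in enumerate(cfg.effects):
            fixed = fixed + eff[self.levels[rows, f]]
        y = fixed[:, None] + self.a[rows] + eps
        y[self.trait2_missing[rows], 1] = np.nan
        self.y[rows] = y

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sire)

    def rows_of_generation(self, g: int) -> np.ndarray:
        return np.nonzero(self.generation == g)[0]

    def n_upto(self, g: int) -> int:
        """Number of animals born in generations 0..g (a birth-order prefix)."""
        return int(np.sum(self.generation <= g))

    def pedigree(self, upto: int | None = None) -> Pedigree:
        n = len(self) if upto is None else self.n_upto(upto)
        return Pedigree(
            sire=self.sire[:n].copy(), dam=self.dam[:n].copy(),
            sex=self.sex[:n].copy(), generation=self.generation[:n].copy(),
            candidate=self.candidate[:n].copy(),
            trait2_missing=self.trait2_missing[:n].copy(),
        )

    def phenotypes(self, upto: int | None = None) -> pd.DataFrame:
        n = len(self) if upto is None else self.n_upto(upto)
        return pd.DataFrame({
            "id": np.arange(1, n + 1),
            "y1": self.y[:n, 0],
            "y2": self.y[:n, 1],
            "f1": self.levels[:n, 0],
            "f2": self.levels[:n, 1],
            "f3": self.levels[:n, 2],
        })


def simulate_founders(config: SchemeConfig, seed=0) -> Population:
    """Convenience constructor for a founder-only population."""
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_gen, rng_res = (np.random.default_rng(s) for s in ss.spawn(3))
    return Population.founders(config, rng_gen, rng_struct, rng_res)
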