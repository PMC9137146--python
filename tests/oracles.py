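"""Dense reference implementations used to validate the sparse machinery.

Everything here favours clarity over speed: the numerator relationship
matrix is built by the tabular method, BLUP by generalised least squares on
the full joint covariance, and the restricted likelihood directly from its
dense definition.  These are only usable on small instances, which is the
point -- the package's sparse implementations must agree with them exactly.
"""

from __future__ import annotations

import numpy as np

UNKNOWN = -1


def tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (no inbreeding
    in the founder population; parents precede offspring)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            A[i, i] = 1.0
        elif s == UNKNOWN or d == UNKNOWN:
            p = s if s != UNKNOWN else d
            A[i, i] = 1.0
            for j in range(i):
                A[i, j] = A[j, i] = 0.5 * A[j, p]
        else:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            for j in range(i):
                A[i, j] = A[j, i] = 0.5 * (A[j, s] + A[j, d])
    return A


def joint_covariance(A, Sigma_a, Sigma_e, obs_trait, obs_animal):
    """Covariance of the stacked observed records.

    ``obs_trait[k]`` (0 or 1) and ``obs_animal[k]`` identify record k; the
    model is y_k = x_k' beta + a[trait_k, animal_k] + e_k with
    cov(a) = Sigma_a (x) A and residuals correlated only within animal.
    """
    m = len(obs_trait)
    V = np.empty((m, m))
    for k in range(m):
        for l in range(m):
            tk, ik = obs_trait[k], obs_animal[k]
            tl, il = obs_trait[l], obs_animal[l]
            V[k, l] = Sigma_a[tk, tl] * A[ik, il]
            if ik == il:
                V[k, l] += Sigma_e[tk, tl]
    return V


def gls_blup(X_rec, y_rec, A, Sigma_a, Sigma_e, obs_trait, obs_animal):
    """GLS fixed effects and BLUP breeding values from the dense joint
    covariance.  Returns (beta, a_hat) with a_hat of shape (n_animals, 2)."""
    V = joint_covariance(A, Sigma_a, Sigma_e, obs_trait, obs_animal)
    Vi = np.linalg.inv(V)
    XtVi = X_rec.T @ Vi
    beta = np.linalg.solve(XtVi @ X_rec, XtVi @ y_rec)
    resid = y_rec - X_rec @ beta
    n = A.shape[0]
    # cov(a_(t,i), y_k) = Sigma_a[t, trait_k] * A[i, animal_k]
    C = np.empty((2 * n, len(y_rec)))
    for t in range(2):
        for i in range(n):
            C[t * n + i] = Sigma_a[t, obs_trait] * A[i, obs_animal]
    a_hat = (C @ (Vi @ resid)).reshape(2, n).T
    return beta, a_hat


def dense_neg2_reml(X_rec, y_rec, A, Sigma_a, Sigma_e, obs_trait, obs_animal):
    """-2 x restricted log-likelihood from the dense definition
    log|V| + log|X'V^-1 X| + y'Py (same constant convention as the MME
    route)."""
    V = joint_covariance(A, Sigma_a, Sigma_e, obs_trait, obs_animal)
    Vi = np.linalg.inv(V)
    XtViX = X_rec.T @ Vi @ X_rec
    beta = np.linalg.solve(XtViX, X_rec.T @ Vi @ y_rec)
    resid = y_rec - X_rec @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return float(ld_V + ld_X + resid @ Vi @ y_rec)


def records_from_phenotypes(y: np.ndarray):
    """Stack observed records trait-major: returns (obs_trait, obs_animal,
    y_rec) for a (n, 2) phenotype array with NaN for missing entries."""
    obs_trait, obs_animal, y_rec = [], [], []
    for t in range(2):
        for i in range(y.shape[0]):
            if np.isfinite(y[i, t]):
                obs_trait.append(t)
                obs_animal.append(i)
                y_rec.append(y[i, t])
    return (np.array(obs_trait), np.array(obs_animal), np.array(y_rec))


def structural_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """A = (I - P)^-1 D (I - P)^-T with P the half-parent links and the
    Mendelian variances D fixed at (1, 3/4, 1/2) by number of known parents.

    This is the relationship matrix the non-inbred A-inverse rules invert
    exactly, on any pedigree; it coincides with the tabular A when no mating
    joins related or inbred parents.
    """
    n = len(sire)
    P = np.zeros((n, n))
    d = np.empty(n)
    for i in range(n):
        known = 0
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                P[i, p] = 0.5
                known += 1
        d[i] = {0: 1.0, 1: 0.75, 2: 0.5}[known]
    M = np.linalg.inv(np.eye(n) - P)
    return M @ np.diag(d) @ M.T


def random_pedigree(n_founders, n_total, rng, no_inbreeding=False):
    """A random valid pedigree: founders first, every later animal gets two
    distinct earlier parents of opposite sex.

    With ``no_inbreeding`` every mating joins animals unrelated under the
    tabular A (falling back to founder status when no such pair exists), so
    the tabular and structural relationship matrices coincide.
    """
    sire = np.full(n_total, UNKNOWN, dtype=np.int64)
    dam = np.full(n_total, UNKNOWN, dtype=np.int64)
    sex = np.array(["M" if rng.random() < 0.5 else "F" for _ in range(n_total)])
    sex[0], sex[1] = "M", "F"  # guarantee one of each among founders
    for i in range(n_founders, n_total):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        if not no_inbreeding:
            sire[i] = rng.choice(males)
            dam[i] = rng.choice(females)
            continue
        A = tabular_a(sire[:i], dam[:i])
        for _ in range(50):
            s = rng.choice(males)
            d = rng.choice(females)
            if A[s, d] == 0.0:
                sire[i], dam[i] = s, d
                break
        # else: left a founder (no unrelated pair found)
    return sire, dam, sex
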