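"""Bivariate animal model against dense GLS / REML oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from copulabv.model import (
    BivariateAnimalModel,
    VarianceComponents,
    genetic_gain,
    heritability,
)
from copulabv.pedigree import Pedigree
from oracles import (
    dense_neg2_reml,
    gls_blup,
    random_pedigree,
    records_from_phenotypes,
    structural_a,
)

VC = VarianceComponents(0.4, 0.1, 0.3, 0.8, -0.2, 0.9)


def _small_instance(seed=0, n=40, missing=True):
    """A <= 50-animal pedigree with simulated bivariate phenotypes."""
    rng = np.random.default_rng(seed)
    sire, dam, sex = random_pedigree(8, n, rng)
    A = structural_a(sire, dam)
    ped = Pedigree(sire=sire, dam=dam, sex=sex,
                   generation=np.zeros(n, dtype=int),
                   candidate=np.ones(n, dtype=bool),
                   trait2_missing=np.zeros(n, dtype=bool))
    Sa = np.array([[0.5, 0.2], [0.2, 0.4]])
    Se = np.array([[1.0, 0.3], [0.3, 0.8]])
    La = np.linalg.cholesky(np.kron(Sa, A))
    a = (La @ rng.standard_normal(2 * n)).reshape(2, n).T
    e = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Se).T
    levels = np.column_stack([rng.integers(3, size=n),
                              rng.integers(2, size=n),
                              rng.integers(2, size=n)])
    effects = (np.array([0.0, 1.0, -1.0]), np.array([0.5, -0.5]),
               np.array([0.3, -0.3]))
    fixed = sum(eff[levels[:, f]] for f, eff in enumerate(effects))
    y = fixed[:, None] + a + e
    if missing:
        y[rng.random(n) < 0.3, 1] = np.nan
        y[0, 1] = np.nan  # ensure at least one missing record
    ph = pd.DataFrame({"id": np.arange(1, n + 1), "y1": y[:, 0], "y2": y[:, 1],
                       "f1": levels[:, 0], "f2": levels[:, 1],
                       "f3": levels[:, 2]})
    return ped, ph, A


def _dense_design(model, obs_trait, obs_animal):
    """Record-level fixed-effect design: trait-block-diagonal copies of X."""
    m = len(obs_trait)
    X_rec = np.zeros((m, 2 * model.p))
    for k in range(m):
        t, i = obs_trait[k], obs_animal[k]
        X_rec[k, t * model.p:(t + 1) * model.p] = model.X[i]
    return X_rec


@pytest.mark.parametrize("missing", [False, True])
@pytest.mark.parametrize("seed", [0, 1])
def test_blup_equals_dense_gls(missing, seed):
    ped, ph, A = _small_instance(seed=seed, missing=missing)
    model = BivariateAnimalModel(ph, ped)
    fe, ebv = model.blup(VC)
    obs_trait, obs_animal, y_rec = records_from_phenotypes(
        ph[["y1", "y2"]].to_numpy())
    X_rec = _dense_design(model, obs_trait, obs_animal)
    beta, a_hat = gls_blup(X_rec, y_rec, A, VC.Sigma_a, VC.Sigma_e,
                           obs_trait, obs_animal)
    assert np.max(np.abs(fe["trait1"].to_numpy() - beta[:model.p])) < 1e-8
    assert np.max(np.abs(fe["trait2"].to_numpy() - beta[model.p:])) < 1e-8
    assert np.max(np.abs(ebv["ebv1"].to_numpy() - a_hat[:, 0])) < 1e-8
    assert np.max(np.abs(ebv["ebv2"].to_numpy() - a_hat[:, 1])) < 1e-8


@pytest.mark.parametrize("missing", [False, True])
def test_restricted_loglik_equals_dense(missing):
    ped, ph, A = _small_instance(seed=2, missing=missing)
    model = BivariateAnimalModel(ph, ped)
    obs_trait, obs_animal, y_rec = records_from_phenotypes(
        ph[["y1", "y2"]].to_numpy())
    X_rec = _dense_design(model, obs_trait, obs_animal)
    for vc in (VC, VarianceComponents(0.3, 0.0, 0.3, 0.7, 0.0, 0.7)):
        dense = dense_neg2_reml(X_rec, y_rec, A, vc.Sigma_a, vc.Sigma_e,
                                obs_trait, obs_animal)
        assert -2.0 * model.loglike(vc) == pytest.approx(dense, abs=1e-7)


def test_canonical_path_equals_generic():
    """The complete-data fast path must agree with the generic assembly."""
    ped, ph, _ = _small_instance(seed=3, missing=False)
    model = BivariateAnimalModel(ph, ped)
    assert model._complete
    for vc in (VC, VarianceComponents(0.18, -0.05, 0.67, 1.0, 0.5, 1.0)):
        fast = model._neg2_loglike_canonical(vc)
        slow, _ = model._neg2_loglike(vc, return_solution=True)
        assert fast == pytest.approx(slow, abs=1e-7)


def test_zero_covariance_decouples_into_univariate():
    """With both covariances pinned at zero the bivariate restricted
    likelihood is the sum of the per-trait univariate ones."""
    ped, ph, A = _small_instance(seed=4, missing=True)
    model = BivariateAnimalModel(ph, ped)
    vc = VarianceComponents(0.5, 0.0, 0.3, 1.1, 0.0, 0.7)
    obs_trait, obs_animal, y_rec = records_from_phenotypes(
        ph[["y1", "y2"]].to_numpy())
    total = 0.0
    for t, (sa, se) in enumerate([(0.5, 1.1), (0.3, 0.7)]):
        keep = obs_trait == t
        X_rec = model.X[obs_animal[keep]]
        total += dense_neg2_reml(
            X_rec, y_rec[keep], A, np.array([[sa]]), np.array([[se]]),
            np.zeros(keep.sum(), dtype=int), obs_animal[keep])
    assert -2.0 * model.loglike(vc) == pytest.approx(total, abs=1e-7)


def test_bivariate_reml_with_fixed_covariances_matches_univariate_fits():
    ped, ph, A = _small_instance(seed=5, missing=False)
    model = BivariateAnimalModel(ph, ped)
    res = model.fit(fix_covariances=True, polish=True)
    assert res.params.sigma_a12 == 0.0 and res.params.sigma_e12 == 0.0
    obs_trait, obs_animal, y_rec = records_from_phenotypes(
        ph[["y1", "y2"]].to_numpy())
    for t, (sa_fit, se_fit) in enumerate([
            (res.params.sigma2_a1, res.params.sigma2_e1),
            (res.params.sigma2_a2, res.params.sigma2_e2)]):
        keep = obs_trait == t
        X_rec = model.X[obs_animal[keep]]

        def univ(z, keep=keep, X_rec=X_rec):
            sa, se = np.exp(z)
            return dense_neg2_reml(
                X_rec, y_rec[keep], A, np.array([[sa]]), np.array([[se]]),
                np.zeros(keep.sum(), dtype=int), obs_animal[keep])

        best = optimize.minimize(univ, np.log([0.3, 0.7]), method="Nelder-Mead",
                                 options=dict(xatol=1e-10, fatol=1e-12))
        sa_ref, se_ref = np.exp(best.x)
        assert sa_fit == pytest.approx(sa_ref, abs=2e-3)
        assert se_fit == pytest.approx(se_ref, abs=2e-3)


def test_fit_recovers_truth_on_moderate_data_and_loglik_monotone():
    ped, ph, _ = _small_instance(seed=6, n=45, missing=True)
    model = BivariateAnimalModel(ph, ped)
    res = model.fit()
    assert res.converged
    path = np.array(res.loglike_path)
    assert np.all(np.diff(path) >= -1e-8)       # monotone accepted iterates
    assert res.loglike == pytest.approx(path[-1])
    # estimates define PD matrices (enforced by the parameterisation)
    assert np.all(np.linalg.eigvalsh(res.params.Sigma_a) > 0)
    assert np.all(np.linalg.eigvalsh(res.params.Sigma_e) > 0)


def test_variance_components_validation_and_round_trip():
    with pytest.raises(ValueError, match="positive definite"):
        VarianceComponents(0.2, 0.5, 0.2, 1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        VarianceComponents(-0.1, 0.0, 0.2, 1.0, 0.0, 1.0)
    z = VC.to_params()
    back = VarianceComponents.from_params(z)
    for f in ("sigma2_a1", "sigma_a12", "sigma2_a2",
              "sigma2_e1", "sigma_e12", "sigma2_e2"):
        assert getattr(back, f) == pytest.approx(getattr(VC, f), abs=1e-12)


def test_heritability_closed_form():
    assert heritability(VarianceComponents(0.18, 0.0, 0.18, 1.0, 0.0, 1.0)
                        )[0] == pytest.approx(0.18 / 1.18)
    vc = VarianceComponents(0.67, 0.0, 0.18, 1.0, 0.0, 1.0)
    h1, h2 = heritability(vc)
    assert h1 == pytest.approx(0.401, abs=5e-4)
    assert h2 == pytest.approx(0.153, abs=5e-4)


def test_genetic_gain_hand_example():
    ebv = pd.DataFrame({
        "id": [1, 2, 3, 4],
        "generation": [0, 0, 2, 2],
        "ebv1": [0.0, 1.0, 2.0, 3.0],
        "ebv2": [0.0, 0.0, 4.0, 0.0],
    })
    g1, g2 = genetic_gain(ebv, 2, (4.0, 4.0))
    assert g1 == pytest.approx((2.5 - 0.5) / 2.0)
    assert g2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        genetic_gain(ebv, 5, (1.0, 1.0))


def test_ebv_table_covers_unphenotyped_animals():
    ped, ph, _ = _small_instance(seed=7, missing=True)
    ph.loc[3, ["y1", "y2"]] = np.nan   # animal with no records at all
    model = BivariateAnimalModel(ph, ped)
    _, ebv = model.blup(VC)
    assert len(ebv) == ped.n
    assert np.all(np.isfinite(ebv[["ebv1", "ebv2"]].to_numpy()))


def test_summary_mentions_key_quantities():
    ped, ph, _ = _small_instance(seed=8, missing=False)
    res = BivariateAnimalModel(ph, ped).fit()
    text = res.summary()
    assert "heritability" in text
    assert "genetic correlation" in text
    assert str(res.model.n) in text
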