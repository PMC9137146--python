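# Methods

This document records the statistical model, the algorithms and the numerical
choices behind `copulabv`, in enough detail to re-derive every number the
package produces.

## 1. Data-generating model

Two traits are measured on each animal. Phenotypes follow the standard
additive animal model

```
y_ij = mu_j + herd_i + season_i + a_ij + e_ij          j = 1, 2
```

with fixed effects (overall mean per trait, plus discrete contemporary-group
factors assigned at birth), additive breeding values `a_i = (a_i1, a_i2)` and
residuals `e_i = (e_i1, e_i2)`.

**Breeding values are always Gaussian.** Founders draw
`a_i ~ N(0, Sigma_a)`; non-founders follow the Mendelian decomposition

```
a_i = (a_sire + a_dam)/2 + m_i,     m_i ~ N(0, Sigma_a / 2)
```

(no inbreeding adjustment of Mendelian-sampling variance; see §8). The
genetic covariance is parameterised through a Kendall tau:
`rho_a = sin(pi * tau_a / 2)`, `sigma_a12 = rho_a * sqrt(sigma2_a1 *
sigma2_a2)`.

**Residuals carry the mis-specification.** Each animal draws a pair
`(u, v)` from a bivariate copula, which is then mapped through the standard
normal quantile function and scaled:

```
e_i1 = sigma_e1 * Phi^{-1}(u),   e_i2 = sigma_e2 * Phi^{-1}(v).
```

Margins are therefore exactly normal — any departure from joint normality
lives purely in the dependence structure.

## 2. Copulas

Four families are implemented, each calibrated by Kendall's tau so that
different dependence *shapes* can be compared at the same dependence
*strength*:

| family  | C(u,v) | tau(theta) | inverse used |
| --- | --- | --- | --- |
| normal  | Gaussian copula, correlation rho | `tau = (2/pi) asin(rho)` | closed form |
| Frank   | `-(1/th) log(1 + (exp(-th u)-1)(exp(-th v)-1)/(exp(-th)-1))` | `1 - 4/th (1 - D1(th))`, `D1` the Debye function | Brent root-find |
| Clayton | `(u^-th + v^-th - 1)^{-1/th}` | `th / (th + 2)` | `th = 2 tau / (1 - tau)` |
| Joe     | `1 - ((1-u)^th + (1-v)^th - (1-u)^th (1-v)^th)^{1/th}` | 1-D integral of the generator ratio, evaluated in log space | Brent root-find |

Clayton and Joe only model positive dependence; for negative tau the package
uses the 270-degree rotation `C_r(u, v) = u - C(u, 1 - v)`, which negates tau
exactly. Frank and normal handle negative tau natively.

**Sampling** uses conditional inversion: draw `u ~ U(0,1)`, `w ~ U(0,1)`, and
solve `C_{2|1}(v | u) = w`. The conditional CDF has a closed-form inverse for
the normal, Frank and Clayton families; for Joe it is inverted by 64
bisection steps (monotone, bracketed on (0,1), accurate to ~5e-20 in `w`).

**Induced Pearson correlation.** Because the margins are standard normal,

```
rho_P = E[Phi^{-1}(U) Phi^{-1}(V)] = ∫∫ x y c(Phi(x), Phi(y)) phi(x) phi(y) dx dy
```

which `pearson_from_copula` evaluates with a tensor-product Gauss–Legendre
rule (default 512 nodes per axis on [-8, 8], i.e. n = 262,144 evaluations).
At tau = 0.4 this yields 0.588 / 0.544 / 0.578 / 0.576 and at tau = 0.7
0.891 / 0.846 / 0.852 / 0.850 for normal / Frank / Clayton / Joe: the
archimedean copulas induce a *weaker* linear correlation than the Gaussian at
equal tau, so a Gaussian-likelihood analysis of archimedean data is handed
both a distorted shape and a shifted linear signal.

**Tail dependence** distinguishes the families qualitatively:
`lambda_L = 2^{-1/theta}` for Clayton (0.862 at tau = 0.7, lower tail),
`lambda_U = 2 - 2^{1/theta}` for Joe (upper tail), and zero in both tails for
the normal and Frank copulas.

## 3. Breeding scheme

The simulated population mimics a closed two-trait pig nucleus:

* founders: 12 sires and 204 dams (17 dams per sire), unrelated;
* discrete generations, fixed litters, no overlapping use of parents;
* **complete design**: 12 offspring per litter (2 males, 10 females), all
  2,448 offspring per generation phenotyped on both traits — 19,800 animals
  after 8 generations;
* **missing design**: 24 offspring per litter (4 males, 20 females); half of
  each litter (2 males, 10 females) is phenotyped on trait 1 only and never
  becomes a parent — 39,384 animals after 8 generations, with the same 2,448
  complete-record selection candidates per generation;
* selection: generations 1–3 pick the next parents at random among
  candidates; from generation 4 on, parents are chosen by within-sire-family
  truncation on the index `I = 0.5 EBV_1 + 0.5 EBV_2` (best male and the 17
  best females of each sire family), giving male and female selected
  fractions of 1/34 ≈ 2.9% and 17/170 = 10%;
* EBVs for selection come from a fresh REML fit + BLUP on all data recorded
  so far (`selection_vc="reml"`), or optionally from BLUP at the true
  variance components (`selection_vc="true"`).

A `scale` knob multiplies sire/dam counts (litter sizes fixed) so tests and
examples can run at 1/4 scale; all counts above are `scale = 1`.

Randomness is split into three independent `numpy` streams spawned from one
`SeedSequence` — pedigree structure/selection ties, genetic effects, and
residuals — so that swapping the residual copula at a fixed seed leaves the
pedigree and every breeding value bit-identical. Monte-Carlo replicates
across copula families are therefore *paired*: they differ only in residuals.

## 4. REML estimation

`BivariateAnimalModel.fit()` maximises the Gaussian restricted likelihood of
the bivariate model over `(Sigma_a, Sigma_e)` regardless of the true residual
copula — deliberately so, since quantifying that mis-specification is the
point. With `V = Var(y)` and `X` the fixed-effect design,

```
-2 l_R(Sigma_a, Sigma_e) = log|V| + log|X' V^{-1} X| + y' P y + const.
```

Rather than forming `V`, the package assembles Henderson's mixed-model
equations

```
[ X'R⁻¹X   X'R⁻¹Z ] [b]   [X'R⁻¹y]
[ Z'R⁻¹X   Z'R⁻¹Z + A⁻¹ ⊗ Sigma_a⁻¹ ] [a] = [Z'R⁻¹y]
```

in sparse form, where `A⁻¹` comes from Henderson's rules for non-inbred
pedigrees (diagonal Mendelian variances `d ∈ {1, 3/4, 1/2}` depending on the
number of known parents; contributions `k = 1/d`, `-k/2`, `k/4`). Records
with a missing trait 2 contribute only the trait-1 block of `R⁻¹`, computed
per missingness pattern. The identity

```
-2 l_R = log|R| + log|G| + log|C| + y' P y + const,
```

with `C` the MME coefficient matrix and `log|A| = Σ log d_i` essentially free,
reduces each likelihood evaluation to one sparse factorisation.

**Parameterisation and optimiser.** The two covariance matrices are
parameterised by the logs of their Cholesky diagonals plus the free
off-diagonal element, which enforces positive-definiteness without
constraints. L-BFGS-B (`ftol = 1e-11`, forward differences with
`eps = 1e-6`) minimises the cached objective; a Nelder–Mead polish is
available (`polish=True`). `fix_covariances=True` pins both covariances at
zero, decoupling the fit into two univariate animal models (used by the
oracle tests). Non-positive-definite proposals raise inside the
factorisation and are rejected with a large objective value.

**BLUP and results.** At the REML optimum the MME solution directly gives
fixed-effect estimates and breeding values for every pedigree member,
phenotyped or not. The results object reports components, heritabilities
`h2_j = sigma2_aj / (sigma2_aj + sigma2_ej)`, genetic/residual correlations,
the likelihood path, and genetic gain in true-genetic-SD units.

## 5. Fast paths

Two exact accelerations make the Monte-Carlo study feasible on one core.

**Canonical transformation (complete records only).** When every animal has
both traits, the generalised eigendecomposition
`Sigma_a T = Sigma_e T diag(lambda)` with `T' Sigma_e T = I` decorrelates the
traits: `y* = Y T` splits the bivariate REML into two univariate animal
models with genetic variance `lambda_j` and residual variance 1, plus the
closed-form constant `(n_rec - p) log|Sigma_e|`. Each objective evaluation
then needs two small univariate factorisations instead of one
double-size bivariate one. The path agrees with the generic path to 1e-9
including constants and is selected automatically.

**Fixed-pattern sparse LDL'.** The MME pattern never changes across REML
iterations — only the numerical values do. `copulabv.sparse_chol` therefore
runs a fill-reducing ordering (minimum-degree on `A'A + A`, obtained once
from SuperLU's symmetric mode) and a symbolic elimination-tree analysis once
per pattern, then reuses them: each iteration is a pure numeric up-looking
LDL' refactorisation in compiled (numba) code, with `log|C| = Σ log D_ii`
read off the factor. The MME itself is assembled as a scalar combination of
eight precomputed parameter-free blocks sharing one union sparsity pattern,
so re-assembly is a few `axpy`s. Compared with calling a general sparse LU
per iteration this is a ~20x speed-up; a full 8-generation replicate at 1/4
scale, including five REML fits for selection, takes about 4 seconds.

## 6. Diagnostics

`copulabv.diagnostics.mardia` computes Mardia's multivariate skewness
`b_{1,p} = mean over (i,k) of ((x_i - m)' S^{-1} (x_k - m))^3` and kurtosis
`b_{2,p} = mean of ((x_i - m)' S^{-1} (x_i - m))^2`, with asymptotic tests
(`n b_{1,p} / 6 ~ chi2`, kurtosis ~ normal around `p(p+2)`). The skewness is
evaluated through the third-central-moment tensor — `O(n)` memory instead of
the naive `n x n` Gram matrix. Under joint normality of two traits the
references are 0 and 8; copula-coupled residual pairs show e.g. skewness
≈ 2.35 and kurtosis ≈ 11.7 for Joe at tau = 0.7 at n = 1000, while the
normal-scores marginal transform leaves each margin exactly Gaussian —
demonstrating that marginal checks cannot detect this mis-specification.

## 7. Monte-Carlo study

`parameter_grid(family)` crosses `tau_a ∈ {0.2, 0.4}`,
`tau_e ∈ {±0.4, ±0.7}` and `sigma2_a ∈ {(0.18,0.18), (0.18,0.67),
(0.67,0.67)}` (residual variances 1, hence true heritabilities 0.153 and
0.401) into 24 parameter sets per copula family. `run_replicate` is a pure
function of `(parameter set, seed, scale, terminal generation, ...)`;
`run_study` derives replicate seeds as
`SeedSequence([seed, set_index, replicate_index])`, shared across families
for pairing, and writes three artifacts: `study_summary.tsv` (bias, SE = SD
across replicates, one-sample t statistic and p-value per quantity and
recorded generation, plus genetic gain relative to the Gaussian-copula
baseline), `raw_estimates.tsv` (every replicate's estimates), and
`manifest.json` (seed, sizes, library versions, per-set replicate seeds).
The reported p-values are per-cell and not adjusted for multiple testing;
the manifest says so.

Failed replicates (non-convergence, singular systems) are counted and
excluded, never silently retried with a new seed.

## 8. Known limitations

* `A⁻¹` uses the non-inbred rules; with 8 closed generations mild inbreeding
  accumulates, so the implied relationship matrix is the structural
  `(I - P)^{-1} D (I - P)^{-T}` with `D ∈ {1, 3/4, 1/2}` rather than the
  inbreeding-adjusted `A`. Simulation and estimation use the *same*
  convention, so this does not by itself bias the copula comparison.
* Mendelian-sampling variance is likewise not reduced for parental
  inbreeding.
* Standard errors of individual REML estimates (average-information matrix)
  are not computed; the study quantifies uncertainty across replicates
  instead.
* The optimiser uses forward-difference gradients; on near-boundary
  problems (genetic variance → 0) `fit()` reports non-convergence rather
  than guessing.
* Only two traits and the four listed copula families are supported.
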