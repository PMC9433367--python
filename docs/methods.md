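# Methods

## Model

`dosem` implements linear Gaussian structural equation models whose causal
structure is an acyclic directed mixed graph (ADMG). Observed variables
`V ∈ R^n` are mean deviations and satisfy

    V = C V + ε,    ε ~ N_n(0, Ψ),

with `C` the matrix of path coefficients (a directed edge `V_i → V_j`
puts the edge's parameter at `C[j, i]`) and `Ψ` the error covariance
(diagonal entries are error variances; an off-diagonal entry — a
bidirected edge — encodes an unobserved common cause of the two
variables). Only recursive systems are supported: the directed part must
be acyclic so that some variable ordering makes `C` strictly lower
triangular and `(I − C)^{-1}` exists. The model-implied joint covariance
is `Σ(θ) = (I − C)^{-1} Ψ (I − C)^{-T}`.

Assumptions inherited from this model class: known causal ordering,
modularity of interventions, no interference between units, homogeneous
and constant direct effects (linearity), multivariate normal errors,
continuous variables measured without error, and a correctly specified
graph. There are no intercepts or mean structures; data are centred at
load time and the means discarded.

Parameters are referred to by labels. Sharing a label across edges
imposes an equality constraint (used, e.g., for time-constant coefficients
in panel models); this is the only constraint mechanism — no general
functional constraints. The free parameter vector is
`θ = (θ_F, θ_P)` with the q structural labels first (first-appearance
order over the directed edge list), then the p covariance labels.
Because `C` and `Ψ` are linear in `θ`, the Jacobians
`∂vec C/∂θ′` and `∂vec Ψ/∂θ′` are constant 0/1 incidence matrices; an
off-diagonal covariance label sets both symmetric vec positions.

## Interventions

`do(x)` on index set `I` (size `K_x`, complement `N`) replaces the
targeted structural equations by constants:

    V = I_N C V + I_N ε + 1_I x
      ⇒ V | do(x) = T1 ε + a1 x,
        T1 = (I − I_N C)^{-1} I_N,  a1 = (I − I_N C)^{-1} 1_I.

`V | do(x)` is a singular n-dimensional Gaussian with mean `a1 x`,
covariance `T1 Ψ T1′` and rank `n − K_x`; the covariance does not depend
on `x`. The covariance is stored full-size with exact zeros in the
interventional rows/columns, and densities are only defined for subsets
of `N` (enforced by `GaussianQuery`). Marginals, densities, interval
probabilities, average treatment effects (`ı_j′ a1 (x − x′)`) and — for
the seeing-vs-doing contrast — ordinary Gaussian conditioning
(Schur complement) are provided. User-facing indexes are 1-based
(variable names are also accepted everywhere); the translation to 0-based
arrays happens once at the API boundary.

Interval probabilities use the exact `Φ` difference in one dimension and
scipy's quasi-Monte-Carlo Gaussian rectangle algorithm (absolute accuracy
about 1e-6) for several outcomes. 95% intervals use the normal quantile
1.959964; values printed with 1.96 still agree at two decimals.

## Causal effect functions and the delta method

Four causal effect functions map `θ` to features of the interventional
distribution, for a fixed intervention index set:

* `g1(θ; x) = (I − I_N C)^{-1} 1_I x` — interventional mean (depends on
  `θ_F` only);
* `g2(θ) = vech(T1 Ψ T1′)` — interventional covariance;
* `g3(θ; x, v_N)` — interventional density (optionally of a marginal
  outcome subset);
* `g4(θ; x, y_low, y_up)` — interval probability of a single outcome.

Their closed-form Jacobians use the Magnus–Neudecker machinery with
column-major `vec`, `vech` stacking the lower triangle including the
diagonal, and the duplication/elimination/commutation matrices `D_n`,
`L_n`, `K_n`:

* `∂g1/∂θ′ = [(x′ 1_I′ M′) ⊗ (M I_N)] ∂vecC/∂θ′` with `M = (I − I_N C)^{-1}`;
* `∂g2/∂θ′ = L_n [(I + K_n)(V ⊗ T1) ∂vecC/∂θ′ + (T1 ⊗ T1) ∂vecΨ/∂θ′]`
  where `V = T1 Ψ T1′`;
* `∂g3/∂θ′` chains the Gaussian score in `(μ, Σ)` of the queried subset
  through the `g1`/`g2` Jacobians;
* `∂g4/∂θ′` chains `−φ` differences in `(μ_y, σ_y²)` through the outcome
  row of `g1` and the `(j, j)` entry of the covariance; it is defined for
  a single outcome only, and a multivariate request raises an error
  rather than falling back to numerics.

Jacobians are returned at full width `q + p` with exact zero columns for
parameters the quantity does not involve; `parameter_mask` recovers the
support. The delta method gives
`AV(√N γ̂) = J AV(√N θ̂) J′`, `ASE = sqrt(diag/N)`, `z = γ̂/ASE`.

A central finite-difference oracle (relative step `1e-6·max(1, |θ_i|)`)
lives in the test suite, not the production path; every closed-form
Jacobian is checked against it on randomized recursive models.

## Estimation

The data enter only through the sample covariance `S` (ML denominator
`N`; `N − 1` available via `ddof`). `θ̂` minimises

    F_ML(θ) = log|Σ(θ)| + tr(S Σ(θ)^{-1}) − log|S| − n ≥ 0,

which is zero iff `Σ(θ) = S`. The analytic gradient is
`Δ_vec′ vec(Σ^{-1}(Σ − S)Σ^{-1})` with
`Δ_vec = (I + K_n)(Σ ⊗ B) ∂vecC/∂θ′ + (B ⊗ B) ∂vecΨ/∂θ′`,
`B = (I − C)^{-1}`; `Δ = L_n Δ_vec` is the vech-Jacobian used throughout.

Numerical choices: the objective is `+inf` whenever `Ψ(θ)` is not
positive definite (Cholesky test; pivot tolerance 1e-10 elsewhere), which
keeps the search inside the parameter space — the likelihood itself sees
only `Σ`, which can be fine while `Ψ` is indefinite. Optimisation runs
L-BFGS-B with the analytic gradient from the default start (path
coefficients 0, error variances from sample variances, covariances 0)
plus four jittered restarts (fixed seed), then polishes every optimum
with Fisher scoring (`H = Δ_vec′(Σ^{-1} ⊗ Σ^{-1})Δ_vec`) using step
halving that, near machine-precision `F`, also accepts steps that shrink
the gradient; the best admissible optimum wins and convergence is
declared at gradient norm below 1e-8.

The asymptotic covariance uses the normal-theory expected information

    AV(√N θ̂) = 2 [Δ′ D_n′ (Σ^{-1} ⊗ Σ^{-1}) D_n Δ]^{-1},

the standard covariance-structure ML form (it reduces to `2ψ²` for a
single free variance); an observed-information variant (numerical Hessian
of `F_ML` against the actual `S`) is available behind a flag.

Local identification is the rank condition `rank(Δ) = q + p`, evaluated
at five random generic draws (singular-value threshold
`max_dim · eps · σ_max · 10³`) and declared only if unanimous; deficient
runs report the labels spanning the null space. This is deliberately a
*local, numerical* check — symbolic/global identification analysis is out
of scope, and users of just-identified-looking models should be aware the
check cannot distinguish local from global uniqueness.

## Synthetic data

`simulate_observational` draws `ε` through the lower-triangular Cholesky
factor of `Ψ` (fixed convention, so a seed pins the table byte for byte)
and applies the reduced form; `simulate_interventional` generates from
the mutilated system directly (zeroed rows of `C`, constant injection),
not by rejection or conditioning, mirroring the do-operator semantics.

The packaged fixture emulates a three-occasion insulin–glucose panel
study: variables `(X1, Y1, X2, Y2, X3, Y3)`, cross-lagged time-constant
coefficients `c_xx = 0.05`, `c_xy = 0.4`, `c_yx = −0.6`, `c_yy = 1.2`,
baseline (co)variances `ψ_x1x1 = 131.76`, `ψ_y1y1 = 632.94`,
`ψ_x1y1 = 254.12`, stationary later-occasion error moments `ψ_xx = 20`,
`ψ_yy = 40`, `ψ_xy = 3`, and serial error covariances `ψ_x1x2 = 15`,
`ψ_x2x3 = 2`, `ψ_y1y2 = 35`, `ψ_y2y3 = 10` (q = 4, p = 10). Insulin is
in mcIU/ml, glucose in mg/dl (both mean-centred); glucose in `[−40, 80]`
defines treatment success. What the generator does **not** emulate:
non-normal errors, measurement error, unit heterogeneity (random
effects), nonlinear effect modification, missing data, or sampling-design
features of real panels — passing tests show the closed forms and their
estimators are internally correct under the model, not that the model
fits any particular real dataset.

## Test and simulation sizes

Monte-Carlo checks use sizes chosen to make sampling error small relative
to the tolerances asserted: interventional-moment agreement at 1e5 draws
(4 MC standard errors), CI coverage of the interventional mean and the
success probability over 1000 replications at N = 500 (93–97% band),
delta-method variance of the interventional glucose variance over 2000
replications, asymptotic-covariance agreement over 1000 replications at
N = 2000 (10% Frobenius-relative), and the `√N` error-halving rate at 60
replications per sample size. Jacobians are verified on 50 randomized
models (relative tolerance 1e-5), rank reduction of `T1` on 100.

## Known limitations

* Recursive models only; cyclic systems and latent-variable measurement
  models are rejected.
* `g4`'s closed-form Jacobian covers a single outcome; multivariate
  interval probabilities have values but no analytic derivatives.
* Conditional (value-dependent) and dynamic interventions are not
  modelled.
* ML under normality only; no GLS/ADF/robust standard errors, no missing
  data handling.
* The dose optimiser assumes a single treatment and single outcome with
  finite bounds; a zero effect slope makes the objective flat and is
  reported as an error rather than an arbitrary optimum.
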