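# dosem

Linear Gaussian causal models on acyclic directed mixed graphs (ADMGs),
with a matrix-algebra do-operator, closed-form interventional
distributions, covariance-based maximum likelihood estimation, and
delta-method asymptotic inference for causal quantities beyond the mean.

## Who this is for

Researchers in biostatistics, epidemiology and the behavioural sciences
who specify their causal assumptions as a linear structural equation model
with possibly correlated errors (an ADMG: directed edges for direct
effects, bidirected edges for unobserved confounding) and want to answer
interventional ("doing") questions — not just conditional ("seeing")
ones — with honest standard errors.

## The model

Observed variables `V = (V_1, …, V_n)` (mean-centred) follow the recursive
system

```
V = C V + ε,    ε ~ N_n(0, Ψ),
```

where `C(θ_F)` holds the path coefficients and `Ψ(θ_P)` the error
(co)variances; labels may be shared across edges to impose equality
constraints. An intervention `do(x)` on index set `I` (complement `N`)
replaces the targeted equations with constants, leaving all others intact
(modularity). In matrix form, with selection matrices `1_I`, `1_N` and the
diagonal 0/1 matrix `I_N`,

```
V | do(x) = T1 ε + a1 x,
T1 = (I − I_N C)^{-1} I_N,    a1 = (I − I_N C)^{-1} 1_I,
```

so `V | do(x)` is the (singular, rank `n − K_x`) Gaussian
`N(a1 x, T1 Ψ T1′)`. Any feature of this distribution is a *causal
quantity* `γ = g(θ)`: the package implements the interventional mean
(`g1`), the half-vectorised interventional covariance (`g2`), the
interventional density (`g3`) and interval probabilities such as the
probability of treatment success (`g4`), together with their closed-form
Jacobians `∂g/∂θ′`. Parameters are estimated by minimising the ML
discrepancy `F_ML(θ) = log|Σ(θ)| + tr(S Σ(θ)^{-1}) − log|S| − n`, and the
delta method propagates `AV(√N θ̂)` through the Jacobians:

```
AV(√N γ̂) = (∂g/∂θ′) AV(√N θ̂) (∂g/∂θ′)′.
```

## Worked example: insulin and glucose

The packaged fixture is a six-variable cross-lagged panel model of blood
insulin (`X_t`, mcIU/ml) and blood glucose (`Y_t`, mg/dl, both
mean-centred) at three occasions, with time-constant coefficients and
baseline confounding. Glucose outside `[−40, 80]` indicates hypo-/
hyperglycemia, so that interval defines treatment success.

```python
import numpy as np
from dosem import (
    illustration_fixture, build_matrices, model_implied_covariance,
    Intervention, selection_matrices, interventional_moments,
    GaussianQuery, interval_probability, conditional_distribution,
)

spec, theta = illustration_fixture()
mats = build_matrices(spec, theta)
sigma = model_implied_covariance(mats)
x2 = np.sqrt(sigma[spec.index("X2"), spec.index("X2")])
print(f"sd(X2)            = {x2:.2f}")

iv = Intervention.from_names(spec, {"X2": 11.54})
dist = interventional_moments(mats, selection_matrices(spec.n, iv), iv)
y3 = spec.index("Y3")
print(f"E(Y3 | do)        = {dist.mean[y3]:.2f}")
print(f"V(Y3 | do)        = {dist.covariance[y3, y3]:.4f}")
q = GaussianQuery.from_names(spec, "Y3", [-40.0], [80.0])
print(f"P(success | do)   = {interval_probability(dist, q):.4f}")

slopes, cond = conditional_distribution(sigma, (spec.index("X2") + 1,), (y3 + 1,))
print(f"E(Y3 | X2=x2)     = {slopes[0, 0]:.2f} * x2")
print(f"V(Y3 | X2)        = {cond[0, 0]:.2f}")
```

prints

```
sd(X2)            = 11.54
E(Y3 | do)        = -6.92
V(Y3 | do)        = 1096.3855
P(success | do)   = 0.8368
E(Y3 | X2=x2)     = 1.76 * x2
V(Y3 | X2)        = 353.99
```

Setting insulin one standard deviation high by *intervention* lowers
expected glucose (−6.92), while *observing* the same insulin level
predicts high glucose (1.76 × 11.54 ≈ 20.3): the seeing/doing contrast.
The interventional variance (1096.4) is also much larger than the
conditional one (354.0), so intervention effects on the full distribution
matter, not just on the mean.

The same workflow is available from the shell:

```
dosem intervene --model illustration --do X2=11.54 --outcome Y3 --bounds -40:80
dosem simulate  --model illustration --n 100 --seed 7 --out panel.csv
dosem fit       --model illustration --data panel.csv --out fit.json
dosem effects   --model illustration --fit fit.json --do X2=11.54 \
                --outcome Y3 --quantity prob --bounds -40:80
dosem optimize  --model illustration --do X2 --outcome Y3 --bounds -40:80
```

## Scope and limits

Recursive (acyclic) models only; no latent variables, mean structures or
conditional/dynamic interventions; ML estimation under multivariate
normality (GLS/ADF/robust variants are out of scope); identification is
checked numerically by the local rank condition on `∂vech Σ/∂θ′`, not by
symbolic global analysis. See `docs/methods.md` for the full methods note.
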