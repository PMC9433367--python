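"""Covariance-based maximum likelihood estimation of linear ADMG models.

The observed-data likelihood depends on the data only through the sample
covariance S, so the model is fitted by minimising the ML discrepancy

    F_ML(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - log|S| - n,

which is nonnegative and zero exactly when Sigma(theta) = S.  The analytic
gradient flows through Delta(theta) = d vech Sigma / d theta', which is
also the object behind the local-identification rank condition (theta is
locally identified at a generic point iff Delta has full column rank q+p)
and the normal-theory expected-information asymptotic covariance

    AV(sqrt(N) theta-hat) = 2 [Delta' D_n'(Sigma^{-1} kron Sigma^{-1}) D_n Delta]^{-1}.

Optimisation is quasi-Newton (L-BFGS-B, analytic gradient) from a default
start (path coefficients 0, error variances from the sample variances,
covariances 0) plus jittered multi-starts, followed by Fisher-scoring
polish to drive the gradient norm below 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .matops import commutation_matrix, elimination_matrix
from .model import (
    ModelError,
    ModelSpec,
    ParameterVector,
    build_matrices,
    derivative_structure,
    model_implied_covariance,
)
from .effects import AsymptoticCovariance

__all__ = [
    "SampleMoments",
    "FitResult",
    "IdentificationReport",
    "sample_moments",
    "ml_fit",
    "av_theta_ml",
    "delta_sigma",
    "local_identification",
]


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance S (variable order matching the spec) and size N."""

    S: np.ndarray
    N: int
    variables: tuple[str, ...]

    def __post_init__(self):
        s = np.asarray(self.S, dtype=float)
        if s.shape != (len(self.variables),) * 2:
            raise ValueError("S shape does not match the variable list")
        if not np.allclose(s, s.T):
            raise ValueError("S must be symmetric")
        if self.N <= len(self.variables):
            raise ValueError("sample size must exceed the number of variables")
        object.__setattr__(self, "S", 0.5 * (s + s.T))


def sample_moments(data: pd.DataFrame, spec: ModelSpec, ddof: int = 0) -> SampleMoments:
    """Center the data and compute S with ML denominator N (``ddof=0``).

    Columns are reordered to the spec's variable order; means are discarded
    (the model has no mean structure).
    """
    x = data.loc[:, list(spec.variables)].to_numpy(dtype=float)
    n_obs = x.shape[0]
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / (n_obs - ddof)
    return SampleMoments(S=s, N=n_obs, variables=spec.variables)


@dataclass(frozen=True)
class IdentificationReport:
    """Rank condition on Delta at several generic parameter points."""

    delta_rank: int
    n_free: int
    locally_identified: bool
    deficient_labels: tuple[str, ...]


@dataclass(frozen=True)
class FitResult:
    theta_hat: ParameterVector
    av_theta: AsymptoticCovariance
    discrepancy: float
    converged: bool
    gradient_norm: float
    identification: IdentificationReport
    N: int

    @property
    def ase(self) -> np.ndarray:
        """Delta-method standard errors of theta-hat at sample size N."""
        return np.sqrt(np.diag(self.av_theta.av_theta) / self.N)

    @property
    def z(self) -> np.ndarray:
        return self.theta_hat.values / self.ase


# ---------------------------------------------------------------------------
# Jacobian of the model-implied covariance


def _vec_jacobian_sigma(spec: ModelSpec, theta: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
    """(vec Sigma Jacobian, Sigma) without symmetry reduction.

    With B = (I - C)^{-1} and Sigma = B Psi B',

        d vec Sigma / d theta' = (I + K_n)(Sigma kron B) dvecC + (B kron B) dvecPsi.
    """
    n = spec.n
    mats = _build_unchecked(spec, theta)
    b = np.linalg.solve(np.eye(n) - mats[0], np.eye(n))
    sigma = b @ mats[1] @ b.T
    deriv = derivative_structure(spec)
    k = commutation_matrix(n)
    jac = (np.eye(n * n) + k) @ np.kron(sigma, b) @ deriv.dvecC + np.kron(b, b) @ deriv.dvecPsi
    return jac, 0.5 * (sigma + sigma.T)


def _build_unchecked(spec: ModelSpec, theta: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
    """(C, Psi) without the positive-definiteness gate (for derivatives/rank)."""
    n = spec.n
    idx = {v: i for i, v in enumerate(spec.variables)}
    values = {**theta.as_dict(), **spec.fixed_values}
    c = np.zeros((n, n))
    for s, t, lab in spec.directed_edges:
        c[idx[t], idx[s]] = values[lab]
    psi = np.zeros((n, n))
    for a, b_, lab in spec.bidirected_edges:
        psi[idx[a], idx[b_]] = psi[idx[b_], idx[a]] = values[lab]
    return c, psi


def delta_sigma(spec: ModelSpec, theta: ParameterVector) -> np.ndarray:
    """Delta = d vech Sigma(theta) / d theta', shape n(n+1)/2 x (q+p).

    Columns of equality-shared labels are sums of the per-position
    derivatives (by linearity of the incidence matrices).
    """
    jac, _ = _vec_jacobian_sigma(spec, theta)
    return elimination_matrix(spec.n) @ jac


# ---------------------------------------------------------------------------
# discrepancy function and fitting


def _fml_and_grad(spec: ModelSpec, values: np.ndarray, template: ParameterVector,
                  S: np.ndarray, logdet_S: float) -> tuple[float, np.ndarray]:
    n = spec.n
    theta = template.replace_values(values)
    # stay inside the parameter space: Psi must be PD, not just Sigma
    _, psi = _build_unchecked(spec, theta)
    try:
        np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(values)
    jac_vec, sigma = _vec_jacobian_sigma(spec, theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(values)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(values)
    f = logdet + float(np.sum(sigma_inv * S)) - logdet_S - n
    inner = sigma_inv - sigma_inv @ S @ sigma_inv
    grad = jac_vec.T @ inner.reshape(-1, order="F")
    return f, grad


def _default_start(spec: ModelSpec, sample: SampleMoments) -> np.ndarray:
    """Path coefficients 0; error variances from sample variances; covariances 0."""
    idx = {v: i for i, v in enumerate(spec.variables)}
    start = {lab: 0.0 for lab in spec.labels}
    var_positions: dict[str, list[int]] = {}
    for a, b, lab in spec.bidirected_edges:
        if a == b and lab not in spec.fixed_values:
            var_positions.setdefault(lab, []).append(idx[a])
    for lab, pos in var_positions.items():
        start[lab] = float(np.mean([sample.S[i, i] for i in pos]))
    return np.asarray([start[lab] for lab in spec.labels])


def ml_fit(
    spec: ModelSpec,
    sample: SampleMoments,
    start: ParameterVector | None = None,
    n_starts: int = 5,
    seed: int = 0,
    information: str = "expected",
) -> FitResult:
    """Minimise F_ML(theta) and package estimates with asymptotics.

    Runs the default (or supplied) start plus ``n_starts - 1`` jittered
    restarts with a fixed seed, keeps the best optimum, and polishes it
    with Fisher scoring until the gradient norm drops below 1e-8.
    Raises :class:`ModelError` when the model is not locally identified.
    """
    if tuple(sample.variables) != spec.variables:
        raise ValueError("sample variable order must match the model spec")
    template = spec.make_theta({lab: 0.0 for lab in spec.labels})
    S = sample.S
    sign_s, logdet_S = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance matrix must be positive definite")

    ident = local_identification(spec, seed=seed)
    if not ident.locally_identified:
        raise ModelError(
            "model is not locally identified; deficient labels: "
            f"{list(ident.deficient_labels)}"
        )

    base = start.values if start is not None else _default_start(spec, sample)
    rng = np.random.default_rng(seed)
    starts = [base]
    scale = np.maximum(np.abs(base), 1.0)
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + 0.1 * scale * rng.standard_normal(base.shape))

    def objective(v):
        return _fml_and_grad(spec, v, template, S, logdet_S)

    # polish every quasi-Newton optimum and keep the best one whose Psi is
    # admissible (the likelihood sees only Sigma, so an unpolished optimum
    # can sit in an indefinite-Psi region even when Sigma is fine)
    best = None
    for s0 in starts:
        res = minimize(
            objective, s0, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if not np.isfinite(res.fun):
            continue
        val, f, grad_norm = _fisher_polish(spec, res.x, template, S, logdet_S)
        try:
            build_matrices(spec, template.replace_values(val))
        except ModelError:
            continue
        if best is None or f < best[1]:
            best = (val, f, grad_norm)

    if best is None:
        raise ModelError(
            "no admissible optimum found (non-convergence or Psi not positive definite)"
        )
    best_val, best_f, grad_norm = best
    theta_hat = template.replace_values(best_val)
    av = av_theta_ml(spec, theta_hat, information=information, S=S)
    return FitResult(
        theta_hat=theta_hat,
        av_theta=av,
        discrepancy=max(best_f, 0.0),
        converged=bool(grad_norm < 1e-8),
        gradient_norm=float(grad_norm),
        identification=ident,
        N=sample.N,
    )


def _fisher_polish(spec, values, template, S, logdet_S, max_iter=60):
    """Fisher-scoring refinement with step halving."""
    f, grad = _fml_and_grad(spec, values, template, S, logdet_S)
    for _ in range(max_iter):
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < 1e-10:
            break
        theta = template.replace_values(values)
        jac_vec, sigma = _vec_jacobian_sigma(spec, theta)
        sigma_inv = np.linalg.inv(sigma)
        info = jac_vec.T @ np.kron(sigma_inv, sigma_inv) @ jac_vec
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        alpha = 1.0
        for _ in range(30):
            f_new, grad_new = _fml_and_grad(spec, values - alpha * step, template, S, logdet_S)
            # near the optimum f changes below machine precision; accept
            # steps that shrink the gradient without raising f
            acceptable = np.isfinite(f_new) and (
                f_new < f - 1e-16
                or (f_new <= f + 1e-13 and np.linalg.norm(grad_new) < 0.9 * grad_norm)
            )
            if acceptable:
                values = values - alpha * step
                f, grad = f_new, grad_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return values, f, float(np.linalg.norm(grad))


# ---------------------------------------------------------------------------
# asymptotic covariance and identification


def av_theta_ml(
    spec: ModelSpec,
    theta_hat: ParameterVector,
    information: str = "expected",
    S: np.ndarray | None = None,
) -> AsymptoticCovariance:
    """Normal-theory AV(sqrt(N) theta-hat) at theta-hat.

    ``expected`` uses the expected-information form
    2 [Delta' D'(Sigma^{-1} kron Sigma^{-1}) D Delta]^{-1}; ``observed``
    inverts twice the numerical Hessian of F_ML at theta-hat against the
    sample covariance ``S`` (defaults to Sigma(theta-hat), in which case
    the two variants coincide at a perfectly fitting solution).
    """
    if information == "expected":
        jac_vec, sigma = _vec_jacobian_sigma(spec, theta_hat)
        sigma_inv = np.linalg.inv(sigma)
        info = 0.5 * jac_vec.T @ np.kron(sigma_inv, sigma_inv) @ jac_vec
    elif information == "observed":
        info = 0.5 * _fml_hessian_at(spec, theta_hat, S=S)
    else:
        raise ValueError("information must be 'expected' or 'observed'")
    try:
        av = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ModelError("information matrix is singular (model not identified?)") from None
    return AsymptoticCovariance(av_theta=0.5 * (av + av.T), source="analytic")


def _fml_hessian_at(
    spec: ModelSpec, theta: ParameterVector, S: np.ndarray | None = None
) -> np.ndarray:
    """Numerical Hessian of F_ML(theta) against S.

    Central differences of the analytic gradient; used by the
    observed-information variant.
    """
    if S is None:
        S = model_implied_covariance(build_matrices(spec, theta))
    _, logdet_S = np.linalg.slogdet(S)
    template = theta
    v0 = theta.values
    k = v0.size
    hess = np.zeros((k, k))
    for i in range(k):
        h = 1e-6 * max(1.0, abs(v0[i]))
        vp, vm = v0.copy(), v0.copy()
        vp[i] += h
        vm[i] -= h
        _, gp = _fml_and_grad(spec, vp, template, S, logdet_S)
        _, gm = _fml_and_grad(spec, vm, template, S, logdet_S)
        hess[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (hess + hess.T)


def local_identification(
    spec: ModelSpec, theta: ParameterVector | None = None, n_draws: int = 5, seed: int = 0
) -> IdentificationReport:
    """Rank condition rank(Delta) = q+p at generic parameter points.

    Evaluates Delta at ``n_draws`` random draws (plus the supplied theta,
    if any); identification is declared only if the rank is full at every
    draw.  When deficient, labels spanning the null space are reported.
    """
    rng = np.random.default_rng(seed)
    n_free = len(spec.labels)
    if n_free == 0:
        return IdentificationReport(0, 0, True, ())
    thetas = []
    if theta is not None:
        thetas.append(theta)
    var_labels = {lab for a, b, lab in spec.bidirected_edges if a == b}
    for _ in range(n_draws):
        values = {}
        for lab in spec.labels_F:
            values[lab] = float(rng.uniform(-0.9, 0.9))
        for lab in spec.labels_P:
            values[lab] = float(rng.uniform(1.0, 2.0)) if lab in var_labels else float(
                rng.uniform(-0.2, 0.2)
            )
        thetas.append(spec.make_theta(values))

    worst_rank = n_free
    null_vec = None
    for th in thetas:
        delta = delta_sigma(spec, th)
        svals = np.linalg.svd(delta, compute_uv=False)
        tol = max(delta.shape) * np.finfo(float).eps * svals[0] * 1e3 if svals.size else 0.0
        rank = int(np.sum(svals > tol))
        if rank < worst_rank:
            worst_rank = rank
            _, _, vt = np.linalg.svd(delta)
            null_vec = np.abs(vt[rank:]).sum(axis=0)
    deficient: tuple[str, ...] = ()
    if worst_rank < n_free and null_vec is not None:
        deficient = tuple(
            lab for lab, w in zip(spec.labels, null_vec) if w > 1e-8
        )
    return IdentificationReport(
        delta_rank=worst_rank,
        n_free=n_free,
        locally_identified=worst_rank == n_free,
        deficient_labels=deficient,
    )
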