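"""Causal effect functions and delta-method asymptotics.

A causal effect function g maps the parameters theta = (theta_F, theta_P)
of the observed-data model onto a causal quantity gamma defined through the
do-operator.  Four basic quantities are covered, all for a fixed
intervention index set I:

* g1(theta; x)            -- the n-vector interventional mean a1(theta_F) x,
* g2(theta)               -- vech of the interventional covariance T1 Psi T1',
* g3(theta; x, v_N)       -- the interventional density of the
                             non-interventional variables at v_N,
* g4(theta; x, y_low, y_up) -- the interval probability for a single
                             outcome variable.

Each has a closed-form Jacobian in theta built from the constant incidence
matrices d vec(C)/d theta', d vec(Psi)/d theta' and the Magnus-Neudecker
constants; the delta method then propagates the asymptotic covariance of
sqrt(N) theta-hat through the Jacobian:

    AV(sqrt(N) gamma-hat) = J AV(sqrt(N) theta-hat) J'.

Jacobians are returned at full width q+p; columns of parameters the
quantity does not depend on are exactly zero (use
:func:`parameter_mask` to drop them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matops import (
    commutation_matrix,
    duplication_matrix,
    elimination_matrix,
    vech,
)
from .model import (
    ModelSpec,
    ParameterVector,
    build_matrices,
    derivative_structure,
)
from .intervention import Intervention, selection_matrices, transformation_matrices

__all__ = [
    "CausalQuantity",
    "AsymptoticCovariance",
    "CausalEffectSystem",
    "delta_av",
    "parameter_mask",
]

_Z95 = 1.959964  # exact 97.5% normal quantile to 6 decimals


@dataclass(frozen=True)
class AsymptoticCovariance:
    """Covariance of sqrt(N) theta-hat with a provenance tag."""

    av_theta: np.ndarray
    source: str = "analytic"  # analytic | estimated

    def __post_init__(self):
        a = np.asarray(self.av_theta, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("av_theta must be square")
        object.__setattr__(self, "av_theta", a)


@dataclass(frozen=True)
class CausalQuantity:
    """Value gamma of a causal effect function plus its Jacobian in theta.

    When asymptotics have been attached, ``ase`` is the delta-method
    standard error of gamma-hat at sample size N, ``z`` the ratio
    gamma-hat / ASE and ``ci95`` the corresponding normal interval.
    """

    kind: str
    value: np.ndarray
    jacobian: np.ndarray
    auxiliary: dict
    av_gamma: np.ndarray | None = None
    ase: np.ndarray | None = None
    z: np.ndarray | None = None
    ci95: np.ndarray | None = None


def delta_av(jacobian: np.ndarray, av_theta: AsymptoticCovariance | np.ndarray) -> np.ndarray:
    """AV(sqrt(N) gamma-hat) = J AV(sqrt(N) theta-hat) J'."""
    av = av_theta.av_theta if isinstance(av_theta, AsymptoticCovariance) else np.asarray(av_theta)
    j = np.atleast_2d(np.asarray(jacobian, dtype=float))
    if j.shape[1] != av.shape[0]:
        raise ValueError(
            f"jacobian has {j.shape[1]} columns but AV(theta) is {av.shape[0]}x{av.shape[1]}"
        )
    out = j @ av @ j.T
    return 0.5 * (out + out.T)


def parameter_mask(jacobian: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Boolean mask of theta entries the quantity actually depends on."""
    j = np.atleast_2d(jacobian)
    return np.any(np.abs(j) > tol, axis=0)


class CausalEffectSystem:
    """g1-g4 and their Jacobians for a fixed intervention index set.

    Parameters
    ----------
    spec
        The symbolic model.
    intervention_indexes
        1-based indexes of the do-variables (or variable names).
    outcome
        Single outcome variable (1-based index or name) used by g4 and its
        Jacobian; optional for the other quantities.
    """

    def __init__(self, spec: ModelSpec, intervention_indexes, outcome=None):
        self.spec = spec
        idx = tuple(
            spec.index(i) + 1 if isinstance(i, str) else int(i) for i in intervention_indexes
        )
        self._iv0 = Intervention(n=spec.n, index_set=idx, levels=np.zeros(len(idx)))
        self.sel = selection_matrices(spec.n, self._iv0)
        self.outcome = spec.index(outcome) + 1 if isinstance(outcome, str) else outcome
        self.deriv = derivative_structure(spec)
        n = spec.n
        self._Ln = elimination_matrix(n)
        self._Dn = duplication_matrix(n)
        self._Kn = commutation_matrix(n)

    # -- internals -----------------------------------------------------
    def _pieces(self, theta: ParameterVector):
        mats = build_matrices(self.spec, theta)
        t1, a1, t2, a2 = transformation_matrices(mats, self.sel)
        return mats, t1, a1, t2, a2

    @property
    def n(self) -> int:
        return self.spec.n

    @property
    def K_x(self) -> int:
        return self._iv0.K_x

    def _x(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape != (self.K_x,):
            raise ValueError(f"x must have length {self.K_x}")
        return x

    def _outcome_index(self) -> int:
        if self.outcome is None:
            raise ValueError("this quantity requires a single outcome variable")
        j = int(self.outcome)
        if j in self._iv0.index_set:
            raise ValueError("outcome must not be an interventional variable")
        return j

    # -- values --------------------------------------------------------
    def g1(self, theta: ParameterVector, x) -> np.ndarray:
        """Interventional mean vector a1 x (depends on theta_F only)."""
        _, _, a1, _, _ = self._pieces(theta)
        return a1 @ self._x(x)

    def g2(self, theta: ParameterVector) -> np.ndarray:
        """vech of the interventional covariance T1 Psi T1'."""
        mats, t1, _, _, _ = self._pieces(theta)
        return vech(t1 @ mats.Psi @ t1.T)

    def _outcome_selector(self, outcomes) -> np.ndarray:
        """Rows selecting an outcome subset of N (default: all of N)."""
        if outcomes is None:
            return self.sel.one_N.T
        idx = tuple(
            self.spec.index(i) + 1 if isinstance(i, str) else int(i) for i in outcomes
        )
        bad = set(idx) & set(self._iv0.index_set)
        if bad:
            raise ValueError(f"outcome indexes {sorted(bad)} are interventional variables")
        return np.eye(self.n)[[i - 1 for i in idx], :]

    def g3(self, theta: ParameterVector, x, v_N, outcomes=None) -> float:
        """Interventional density at v_N.

        By default the joint density of all non-interventional variables;
        ``outcomes`` restricts to the marginal density of a subset of N.
        """
        mats, t1, a1, _, _ = self._pieces(theta)
        r = self._outcome_selector(outcomes)
        v_N = np.atleast_1d(np.asarray(v_N, dtype=float))
        mu = r @ a1 @ self._x(x)
        cov = r @ t1 @ mats.Psi @ t1.T @ r.T
        return float(stats.multivariate_normal.pdf(v_N, mean=mu, cov=cov))

    def g4(self, theta: ParameterVector, x, y_low: float, y_up: float) -> float:
        """Interval probability for the single outcome under do(x)."""
        j = self._outcome_index()
        mats, t1, a1, _, _ = self._pieces(theta)
        mu = float((a1 @ self._x(x))[j - 1])
        sd = float(np.sqrt((t1 @ mats.Psi @ t1.T)[j - 1, j - 1]))
        return float(stats.norm.cdf((y_up - mu) / sd) - stats.norm.cdf((y_low - mu) / sd))

    # -- Jacobians -----------------------------------------------------
    def jacobian_g1(self, theta: ParameterVector, x) -> np.ndarray:
        """d g1 / d theta' = [(x' 1_I' M') kron (M I_N)] d vec C / d theta'."""
        x = self._x(x)
        mats, t1, a1, _, _ = self._pieces(theta)
        n = self.n
        m = np.linalg.solve(np.eye(n) - self.sel.I_N @ mats.C, np.eye(n))
        left = (x @ self.sel.one_I.T @ m.T).reshape(1, n)
        return np.kron(left, m @ self.sel.I_N) @ self.deriv.dvecC

    def jacobian_g2(self, theta: ParameterVector) -> np.ndarray:
        """d g2 / d theta' = L_n [G2C dvecC + G2P dvecPsi].

        With V = T1 Psi T1', the chain rule gives
        G2C = (I + K_n)(V kron T1) and G2P = T1 kron T1.
        """
        mats, t1, _, _, _ = self._pieces(theta)
        n = self.n
        v = t1 @ mats.Psi @ t1.T
        g2c = (np.eye(n * n) + self._Kn) @ np.kron(v, t1)
        g2p = np.kron(t1, t1)
        return self._Ln @ (g2c @ self.deriv.dvecC + g2p @ self.deriv.dvecPsi)

    def jacobian_g3(self, theta: ParameterVector, x, v_N, outcomes=None) -> np.ndarray:
        """Chain rule of the (marginal) density through (mu, Sigma) of the subset."""
        mats, t1, a1, _, _ = self._pieces(theta)
        r = self._outcome_selector(outcomes)
        v_N = np.atleast_1d(np.asarray(v_N, dtype=float))
        x = self._x(x)
        mu = r @ a1 @ x
        cov = r @ t1 @ mats.Psi @ t1.T @ r.T
        dens = float(stats.multivariate_normal.pdf(v_N, mean=mu, cov=cov))
        resid = v_N - mu
        cov_inv = np.linalg.inv(cov)
        g3_mu = (resid @ cov_inv).reshape(1, -1)
        g3_sigma = 0.5 * (
            np.kron(resid, resid) @ np.kron(cov_inv, cov_inv) - cov_inv.reshape(-1, order="F")
        ).reshape(1, -1)
        top = r @ self.jacobian_g1(theta, x)
        bottom = np.kron(r, r) @ self._Dn @ self.jacobian_g2(theta)
        return dens * (g3_mu @ top + g3_sigma @ bottom)

    def jacobian_g4(self, theta: ParameterVector, x, y_low: float, y_up: float) -> np.ndarray:
        """Chain rule of the Phi difference through (mu_y, sigma_y^2).

        Only defined for a single outcome variable; multivariate interval
        probabilities have no closed-form Jacobian here.
        """
        j = self._outcome_index()
        mats, t1, a1, _, _ = self._pieces(theta)
        x = self._x(x)
        mu = float((a1 @ x)[j - 1])
        var = float((t1 @ mats.Psi @ t1.T)[j - 1, j - 1])
        sd = np.sqrt(var)
        u_up = (y_up - mu) / sd
        u_low = (y_low - mu) / sd
        phi_up = stats.norm.pdf(u_up) if np.isfinite(u_up) else 0.0
        phi_low = stats.norm.pdf(u_low) if np.isfinite(u_low) else 0.0
        g4_mu = -(phi_up - phi_low) / sd
        g4_var = -(phi_up * u_up - phi_low * u_low) / (2.0 * var)
        n = self.n
        e_j = np.zeros((1, n))
        e_j[0, j - 1] = 1.0
        e_jj = np.zeros((1, n * n))
        e_jj[0, (j - 1) * n + (j - 1)] = 1.0
        d_mu = e_j @ self.jacobian_g1(theta, x)
        d_var = e_jj @ self._Dn @ self.jacobian_g2(theta)
        return g4_mu * d_mu + g4_var * d_var

    # -- packaged quantities -------------------------------------------
    def quantity(self, kind: str, theta: ParameterVector, **aux) -> CausalQuantity:
        """Evaluate a causal quantity and its Jacobian in one shot.

        ``kind`` is one of ``mean``, ``vech-covariance``, ``pdf``,
        ``interval-probability``; auxiliary arguments (x, v_N, y_low, y_up)
        are passed by keyword as applicable.
        """
        if kind == "mean":
            value = self.g1(theta, aux["x"])
            jac = self.jacobian_g1(theta, aux["x"])
        elif kind == "vech-covariance":
            value = self.g2(theta)
            jac = self.jacobian_g2(theta)
        elif kind == "pdf":
            value = np.atleast_1d(self.g3(theta, aux["x"], aux["v_N"], aux.get("outcomes")))
            jac = self.jacobian_g3(theta, aux["x"], aux["v_N"], aux.get("outcomes"))
        elif kind == "interval-probability":
            value = np.atleast_1d(self.g4(theta, aux["x"], aux["y_low"], aux["y_up"]))
            jac = self.jacobian_g4(theta, aux["x"], aux["y_low"], aux["y_up"])
        else:
            raise ValueError(f"unknown quantity kind {kind!r}")
        return CausalQuantity(kind=kind, value=np.atleast_1d(value), jacobian=jac, auxiliary=aux)

    def with_asymptotics(
        self, cq: CausalQuantity, av_theta: AsymptoticCovariance | np.ndarray, N: int
    ) -> CausalQuantity:
        """Attach delta-method ASEs, z-values and 95% CIs to a quantity."""
        av_gamma = delta_av(cq.jacobian, av_theta)
        ase = np.sqrt(np.clip(np.diag(av_gamma), 0.0, None) / N)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(ase > 0, cq.value / ase, np.nan)
        ci = np.stack([cq.value - _Z95 * ase, cq.value + _Z95 * ase], axis=-1)
        return CausalQuantity(
            kind=cq.kind,
            value=cq.value,
            jacobian=cq.jacobian,
            auxiliary=cq.auxiliary,
            av_gamma=av_gamma,
            ase=ase,
            z=z,
            ci95=ci,
        )
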