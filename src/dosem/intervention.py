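"""The matrix do-operator and closed-form interventional distributions.

An intervention do(x) on the index set I replaces the structural equations
of the targeted variables with the constants x, leaving every other
equation intact (modularity).  In matrix form the mutilated system

    V = I_N C V + I_N eps + 1_I x

has the reduced form V | do(x) = T1 eps + a1 x with

    T1 = (I - I_N C)^{-1} I_N,      a1 = (I - I_N C)^{-1} 1_I,

so the interventional distribution is the (singular, rank n - K_x)
Gaussian N(a1 x, T1 Psi T1').  Here 1_I and 1_N are the column-selection
matrices of the interventional and non-interventional coordinates and I_N
is the diagonal 0/1 matrix of the non-interventional ones.

Indexes are 1-based at the API boundary (variable names are also accepted)
and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .model import ModelSpec, StructuralMatrices

__all__ = [
    "Intervention",
    "SelectionMatrices",
    "InterventionalDistribution",
    "GaussianQuery",
    "FlatObjectiveError",
    "selection_matrices",
    "transformation_matrices",
    "interventional_moments",
    "marginal_interventional",
    "interventional_pdf",
    "interval_probability",
    "average_treatment_effect",
    "conditional_distribution",
    "success_probability",
    "optimal_intervention_level",
    "optimal_intervention_for_model",
]


class FlatObjectiveError(ValueError):
    """The success probability does not depend on the interventional level."""


@dataclass(frozen=True)
class Intervention:
    """do(x) on a subset of variables.

    ``index_set`` holds 1-based variable indexes, ascending; ``levels`` the
    interventional values in the same order.  An empty index set denotes
    the observational (no-intervention) case.
    """

    n: int
    index_set: tuple[int, ...]
    levels: np.ndarray

    def __post_init__(self):
        idx = tuple(int(i) for i in self.index_set)
        if any(i < 1 or i > self.n for i in idx):
            raise ValueError("interventional indexes must lie in 1..n")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate interventional indexes")
        object.__setattr__(self, "index_set", tuple(sorted(idx)))
        lv = np.atleast_1d(np.asarray(self.levels, dtype=float))
        if lv.shape != (len(idx),):
            raise ValueError("levels must match the number of interventional indexes")
        # keep levels aligned with the sorted index order
        order = np.argsort(np.asarray(idx))
        object.__setattr__(self, "levels", lv[order])

    @classmethod
    def from_names(cls, spec: ModelSpec, assignments: dict[str, float]) -> "Intervention":
        pairs = sorted((spec.index(v) + 1, x) for v, x in assignments.items())
        return cls(
            n=spec.n,
            index_set=tuple(i for i, _ in pairs),
            levels=np.asarray([x for _, x in pairs]),
        )

    @property
    def K_x(self) -> int:
        return len(self.index_set)

    @property
    def complement(self) -> tuple[int, ...]:
        """Ordered 1-based index set N of non-interventional variables."""
        return tuple(i for i in range(1, self.n + 1) if i not in self.index_set)


@dataclass(frozen=True)
class SelectionMatrices:
    """0/1 selectors 1_I (n x K_x), 1_N (n x (n-K_x)) and diagonal I_N."""

    one_I: np.ndarray
    one_N: np.ndarray
    I_N: np.ndarray


def selection_matrices(n: int, intervention: Intervention) -> SelectionMatrices:
    """Build the selection matrices of an intervention on 1..n."""
    if intervention.n != n:
        raise ValueError("intervention was built for a different n")
    eye = np.eye(n)
    cols_I = [i - 1 for i in intervention.index_set]
    cols_N = [i - 1 for i in intervention.complement]
    one_I = eye[:, cols_I] if cols_I else np.zeros((n, 0))
    one_N = eye[:, cols_N] if cols_N else np.zeros((n, 0))
    return SelectionMatrices(one_I=one_I, one_N=one_N, I_N=one_N @ one_N.T)


def transformation_matrices(
    mats: StructuralMatrices, sel: SelectionMatrices
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(T1, a1, T2, a2) of the mutilated reduced form.

    T1 has rank n - K_x and T2 = 1_N' T1 full row rank n - K_x.
    """
    n = mats.n
    m = np.linalg.solve(np.eye(n) - sel.I_N @ mats.C, np.eye(n))
    t1 = m @ sel.I_N
    a1 = m @ sel.one_I
    t2 = sel.one_N.T @ t1
    a2 = sel.one_N.T @ a1
    return t1, a1, t2, a2


@dataclass(frozen=True)
class InterventionalDistribution:
    """Singular n-dimensional Gaussian of V | do(x).

    The covariance is stored full-size with exact zeros in the
    interventional rows and columns; densities are defined only for
    sub-vectors of the non-interventional set N.
    """

    mean: np.ndarray
    covariance: np.ndarray
    intervention: Intervention
    T1: np.ndarray = field(repr=False)
    a1: np.ndarray = field(repr=False)
    T2: np.ndarray = field(repr=False)
    a2: np.ndarray = field(repr=False)

    @property
    def rank(self) -> int:
        return self.intervention.n - self.intervention.K_x


def interventional_moments(
    mats: StructuralMatrices, sel: SelectionMatrices, intervention: Intervention
) -> InterventionalDistribution:
    """Mean a1 x and covariance T1 Psi T1' of V | do(x).

    The covariance does not depend on the interventional levels x.
    """
    t1, a1, t2, a2 = transformation_matrices(mats, sel)
    x = intervention.levels
    mean = a1 @ x if intervention.K_x else np.zeros(mats.n)
    cov = t1 @ mats.Psi @ t1.T
    # zero out round-off in the deterministic rows/columns
    for i in intervention.index_set:
        cov[i - 1, :] = 0.0
        cov[:, i - 1] = 0.0
    return InterventionalDistribution(
        mean=mean, covariance=cov, intervention=intervention, T1=t1, a1=a1, T2=t2, a2=a2
    )


@dataclass(frozen=True)
class GaussianQuery:
    """Outcome subset and optional interval bounds.

    ``outcome_indexes`` are 1-based and must be non-interventional; bounds
    are componentwise with +-inf allowed.
    """

    outcome_indexes: tuple[int, ...]
    y_low: np.ndarray | None = None
    y_up: np.ndarray | None = None

    def __post_init__(self):
        idx = tuple(int(i) for i in self.outcome_indexes)
        object.__setattr__(self, "outcome_indexes", idx)
        for name in ("y_low", "y_up"):
            val = getattr(self, name)
            if val is not None:
                arr = np.atleast_1d(np.asarray(val, dtype=float))
                if arr.shape != (len(idx),):
                    raise ValueError(f"{name} must have one entry per outcome")
                object.__setattr__(self, name, arr)
        if self.y_low is not None and self.y_up is not None:
            if not np.all(self.y_low < self.y_up):
                raise ValueError("bounds must satisfy y_low < y_up componentwise")

    @classmethod
    def from_names(cls, spec: ModelSpec, outcomes, y_low=None, y_up=None) -> "GaussianQuery":
        if isinstance(outcomes, str):
            outcomes = [outcomes]
        return cls(tuple(spec.index(v) + 1 for v in outcomes), y_low, y_up)


def _check_query(dist: InterventionalDistribution, query: GaussianQuery) -> list[int]:
    bad = set(query.outcome_indexes) & set(dist.intervention.index_set)
    if bad:
        raise ValueError(f"outcome indexes {sorted(bad)} are interventional variables")
    return [i - 1 for i in query.outcome_indexes]


def marginal_interventional(
    dist: InterventionalDistribution, query: GaussianQuery
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal (mean, covariance) of the outcome subset under do(x)."""
    rows = _check_query(dist, query)
    return dist.mean[rows], dist.covariance[np.ix_(rows, rows)]


def interventional_pdf(
    dist: InterventionalDistribution, query: GaussianQuery, values
) -> float:
    """Gaussian density of the queried outcomes at ``values`` under do(x)."""
    mu, cov = marginal_interventional(dist, query)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if len(query.outcome_indexes) == 1:
        return float(stats.norm.pdf(values[0], loc=mu[0], scale=np.sqrt(cov[0, 0])))
    return float(stats.multivariate_normal.pdf(values, mean=mu, cov=cov))


def interval_probability(dist: InterventionalDistribution, query: GaussianQuery) -> float:
    """P(y_low <= Y <= y_up | do(x)) for the queried outcome subset.

    Univariate queries use the exact Phi difference; multivariate ones the
    quasi-Monte-Carlo Gaussian rectangle algorithm (abs. accuracy ~1e-6).
    """
    if query.y_low is None or query.y_up is None:
        raise ValueError("interval_probability requires both bounds")
    mu, cov = marginal_interventional(dist, query)
    if len(query.outcome_indexes) == 1:
        sd = np.sqrt(cov[0, 0])
        return float(
            stats.norm.cdf((query.y_up[0] - mu[0]) / sd)
            - stats.norm.cdf((query.y_low[0] - mu[0]) / sd)
        )
    mvn = stats.multivariate_normal(mean=mu, cov=cov, allow_singular=False)
    return float(mvn.cdf(query.y_up, lower_limit=query.y_low))


def average_treatment_effect(
    mats: StructuralMatrices, outcome: int, treatment: int, x: float, x_prime: float
) -> float:
    """ATE i_j' a1 (x - x') of do(treatment=x) vs do(treatment=x') on the outcome.

    ``outcome`` and ``treatment`` are 1-based variable indexes.
    """
    if outcome == treatment:
        raise ValueError("outcome and treatment must differ")
    iv = Intervention(n=mats.n, index_set=(treatment,), levels=np.array([0.0]))
    sel = selection_matrices(mats.n, iv)
    _, a1, _, _ = transformation_matrices(mats, sel)
    return float(a1[outcome - 1, 0] * (x - x_prime))


def conditional_distribution(
    sigma: np.ndarray, condition_set: tuple[int, ...], target_set: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditioning of the targets on the conditioning set.

    Returns the matrix of regression slopes B (targets x conditioners, so
    the conditional mean at observed values z is B z for mean-centred
    variables) and the conditional covariance (Schur complement).  All
    indexes 1-based.  With an empty conditioning set this is the marginal.
    """
    t = [i - 1 for i in target_set]
    c = [i - 1 for i in condition_set]
    s_tt = sigma[np.ix_(t, t)]
    if not c:
        return np.zeros((len(t), 0)), s_tt
    s_tc = sigma[np.ix_(t, c)]
    s_cc = sigma[np.ix_(c, c)]
    slopes = np.linalg.solve(s_cc, s_tc.T).T
    return slopes, s_tt - slopes @ s_tc.T


# ---------------------------------------------------------------------------
# univariate treatment-success machinery


def success_probability(slope: float, variance: float, x: float, y_low: float, y_up: float) -> float:
    """P(y_low <= Y <= y_up | do(x)) when E(Y|do(x)) = slope*x, V(Y|do(x)) = variance."""
    sd = np.sqrt(variance)
    mu = slope * x
    return float(stats.norm.cdf((y_up - mu) / sd) - stats.norm.cdf((y_low - mu) / sd))


def optimal_intervention_level(
    slope: float,
    variance: float,
    y_low: float,
    y_up: float,
    search: tuple[float, float] = (-100.0, 100.0),
) -> tuple[float, float]:
    """Interventional level maximising the interval probability.

    For slope != 0 the objective is unimodal with the optimum where the
    interventional mean sits at the bound midpoint, i.e. at
    x* = (y_low + y_up) / (2 slope); bounded scalar minimisation (xatol
    1e-8) is used and agrees with that closed form whenever the midpoint
    lies inside the search interval.  A zero slope makes the objective
    flat, which is reported as :class:`FlatObjectiveError`.
    """
    if not (np.isfinite(y_low) and np.isfinite(y_up)):
        raise ValueError("optimal level search requires finite bounds")
    if slope == 0.0:
        raise FlatObjectiveError("treatment has no effect on the outcome mean; objective is flat")
    res = minimize_scalar(
        lambda x: -success_probability(slope, variance, x, y_low, y_up),
        bounds=search,
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


def optimal_intervention_for_model(
    mats: StructuralMatrices,
    treatment: int,
    outcome: int,
    y_low: float,
    y_up: float,
    search: tuple[float, float] = (-100.0, 100.0),
) -> tuple[float, float]:
    """Model-based optimal level: slope and variance from the do-operator."""
    iv = Intervention(n=mats.n, index_set=(treatment,), levels=np.array([0.0]))
    sel = selection_matrices(mats.n, iv)
    dist = interventional_moments(mats, sel, iv)
    slope = float(dist.a1[outcome - 1, 0])
    variance = float(dist.covariance[outcome - 1, outcome - 1])
    return optimal_intervention_level(slope, variance, y_low, y_up, search)
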