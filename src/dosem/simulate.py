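"""Seeded data generation and the packaged insulin-glucose panel model.

Observational data are drawn from the reduced form V = (I - C)^{-1} eps
with eps ~ N_n(0, Psi); interventional data from the mutilated system

    V = I_N C V + I_N eps + 1_I x,

i.e. the equations of the do-variables are replaced by the constants x and
everything else is generated unchanged, mirroring the modularity semantics
of the do-operator.  Errors are drawn through the lower-triangular Cholesky
factor of Psi so that a seed pins down the table byte for byte.

The packaged fixture is a 6-variable cross-lagged panel model of blood
insulin (X_t, mcIU/ml) and blood glucose (Y_t, mg/dl), both mean-centred,
measured at three occasions: directed edges X_{t-1} -> X_t (c_xx),
Y_{t-1} -> X_t (c_xy), X_{t-1} -> Y_t (c_yx), Y_{t-1} -> Y_t (c_yy) with
time-constant coefficients, a bidirected edge X_1 <-> Y_1 (baseline
confounding), contemporaneous error covariances psi_xy at t = 2, 3 and
lag-1 serial error covariances within each series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervention import Intervention
from .model import ModelSpec, ParameterVector, StructuralMatrices, build_matrices

__all__ = [
    "simulate_observational",
    "simulate_interventional",
    "illustration_spec",
    "illustration_theta",
    "illustration_fixture",
]


def _error_factor(mats: StructuralMatrices) -> np.ndarray:
    # fixed factorisation convention so seeds are portable
    return np.linalg.cholesky(mats.Psi)


def _draw_errors(mats: StructuralMatrices, n_units: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n_units, mats.n))
    return z @ _error_factor(mats).T


def simulate_observational(
    spec: ModelSpec, theta: ParameterVector, n_units: int, seed: int
) -> pd.DataFrame:
    """N i.i.d. rows from the reduced form; columns in spec variable order."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    mats = build_matrices(spec, theta)
    rng = np.random.default_rng(seed)
    eps = _draw_errors(mats, n_units, rng)
    b = np.linalg.solve(np.eye(mats.n) - mats.C, np.eye(mats.n))
    return pd.DataFrame(eps @ b.T, columns=list(spec.variables))


def simulate_interventional(
    spec: ModelSpec,
    theta: ParameterVector,
    intervention: Intervention,
    n_units: int,
    seed: int,
) -> pd.DataFrame:
    """N i.i.d. rows from the mutilated system under do(x).

    Interventional columns are constant at their levels; the remaining
    columns follow the closed-form interventional distribution.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    mats = build_matrices(spec, theta)
    n = mats.n
    rng = np.random.default_rng(seed)
    eps = _draw_errors(mats, n_units, rng)
    i_n = np.ones(n)
    shift = np.zeros(n)
    for pos, level in zip(intervention.index_set, intervention.levels):
        i_n[pos - 1] = 0.0
        shift[pos - 1] = level
    cn = i_n[:, None] * mats.C  # rows of do-variables zeroed
    b = np.linalg.solve(np.eye(n) - cn, np.eye(n))
    data = (i_n * eps + shift) @ b.T
    return pd.DataFrame(data, columns=list(spec.variables))


# ---------------------------------------------------------------------------
# insulin-glucose panel fixture


def illustration_spec() -> ModelSpec:
    """The 6-variable insulin-glucose panel ADMG (order X1,Y1,X2,Y2,X3,Y3)."""
    return ModelSpec(
        variables=("X1", "Y1", "X2", "Y2", "X3", "Y3"),
        directed_edges=(
            ("X1", "X2", "c_xx"),
            ("Y1", "X2", "c_xy"),
            ("X1", "Y2", "c_yx"),
            ("Y1", "Y2", "c_yy"),
            ("X2", "X3", "c_xx"),
            ("Y2", "X3", "c_xy"),
            ("X2", "Y3", "c_yx"),
            ("Y2", "Y3", "c_yy"),
        ),
        bidirected_edges=(
            ("X1", "X1", "psi_x1x1"),
            ("Y1", "Y1", "psi_y1y1"),
            ("X1", "Y1", "psi_x1y1"),
            ("X2", "X2", "psi_xx"),
            ("Y2", "Y2", "psi_yy"),
            ("X2", "Y2", "psi_xy"),
            ("X1", "X2", "psi_x1x2"),
            ("X2", "X3", "psi_x2x3"),
            ("Y1", "Y2", "psi_y1y2"),
            ("Y2", "Y3", "psi_y2y3"),
            ("X3", "X3", "psi_xx"),
            ("Y3", "Y3", "psi_yy"),
            ("X3", "Y3", "psi_xy"),
        ),
    )


#: population values of the panel model (time-2/3 error moments shared)
POPULATION_VALUES: dict[str, float] = {
    "c_xx": 0.05,
    "c_xy": 0.4,
    "c_yx": -0.6,
    "c_yy": 1.2,
    "psi_x1x1": 131.76,
    "psi_y1y1": 632.94,
    "psi_x1y1": 254.12,
    "psi_xx": 20.0,
    "psi_yy": 40.0,
    "psi_xy": 3.0,
    "psi_x1x2": 15.0,
    "psi_x2x3": 2.0,
    "psi_y1y2": 35.0,
    "psi_y2y3": 10.0,
}


def illustration_theta(spec: ModelSpec | None = None) -> ParameterVector:
    """Population parameter vector of the panel fixture (q=4, p=10)."""
    spec = spec or illustration_spec()
    return spec.make_theta(POPULATION_VALUES)


def illustration_fixture() -> tuple[ModelSpec, ParameterVector]:
    """(spec, population theta) of the insulin-glucose panel model."""
    spec = illustration_spec()
    return spec, illustration_theta(spec)
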