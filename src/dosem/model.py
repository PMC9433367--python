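"""Symbolic specification of linear Gaussian ADMG models.

A model over variables V = (V_1, ..., V_n) is the recursive linear system

    V = C V + eps,          eps ~ N_n(0, Psi),

where C holds the path coefficients of the directed edges (acyclic, so C is
strictly lower triangular under a topological order) and Psi the error
(co)variances: diagonal entries are error variances, off-diagonal entries
correspond to bidirected edges (unobserved confounding).  All variables are
mean deviations; there are no intercepts.

Parameters are referred to by *labels*.  The same label may be attached to
several edges, which imposes an equality constraint (e.g. time-constant
cross-lagged coefficients in a panel model).  A label never appears on both
a directed and a bidirected edge.  The free parameter vector is

    theta = (theta_F, theta_P)

with the q structural labels first (first-appearance order over the directed
edge list) followed by the p covariance labels (first-appearance order over
the bidirected edge list).  Labels listed in ``fixed_values`` are excluded
from theta and held constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "StructuralMatrices",
    "DerivativeStructure",
    "build_matrices",
    "model_implied_covariance",
    "derivative_structure",
    "load_spec",
]

#: pivot tolerance below which Psi is declared not positive definite
_PD_TOL = 1e-10


class ModelError(ValueError):
    """Invalid model specification or parameter values."""


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic ADMG: variables, labelled directed and bidirected edges.

    Parameters
    ----------
    variables
        Ordered variable names; defines row/column order of C, Psi, Sigma.
    directed_edges
        Tuples ``(source, target, label)``; an edge source -> target places
        the label's value at C[target, source].
    bidirected_edges
        Tuples ``(v1, v2, label)``; self-pairs declare error variances.
        Every variable must have its error variance declared.
    fixed_values
        Labels held at a constant value, excluded from theta.
    """

    variables: tuple[str, ...]
    directed_edges: tuple[tuple[str, str, str], ...]
    bidirected_edges: tuple[tuple[str, str, str], ...]
    fixed_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "directed_edges", tuple(tuple(e) for e in self.directed_edges))
        object.__setattr__(self, "bidirected_edges", tuple(tuple(e) for e in self.bidirected_edges))
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        names = self.variables
        if len(set(names)) != len(names):
            raise ModelError("duplicate variable names")
        idx = {v: i for i, v in enumerate(names)}
        for s, t, _ in self.directed_edges:
            if s not in idx or t not in idx:
                raise ModelError(f"directed edge refers to unknown variable: {s}->{t}")
            if s == t:
                raise ModelError(f"self-loop {s}->{t} not allowed")
        for a, b, _ in self.bidirected_edges:
            if a not in idx or b not in idx:
                raise ModelError(f"bidirected edge refers to unknown variable: {a}<->{b}")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from((s, t) for s, t, _ in self.directed_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ModelError("directed part contains a cycle; only recursive models are supported")
        declared_var = {a for a, b, _ in self.bidirected_edges if a == b}
        missing = set(names) - declared_var
        if missing:
            raise ModelError(f"error variance not declared for: {sorted(missing)}")
        f_labels = {lab for _, _, lab in self.directed_edges}
        p_labels = {lab for _, _, lab in self.bidirected_edges}
        clash = f_labels & p_labels
        if clash:
            raise ModelError(f"labels used on both directed and bidirected edges: {sorted(clash)}")

    # -- derived structure --------------------------------------------
    @property
    def n(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.variables.index(name)

    @property
    def labels_F(self) -> tuple[str, ...]:
        """Free structural labels, first-appearance order."""
        seen: list[str] = []
        for _, _, lab in self.directed_edges:
            if lab not in seen and lab not in self.fixed_values:
                seen.append(lab)
        return tuple(seen)

    @property
    def labels_P(self) -> tuple[str, ...]:
        """Free covariance labels, first-appearance order."""
        seen: list[str] = []
        for _, _, lab in self.bidirected_edges:
            if lab not in seen and lab not in self.fixed_values:
                seen.append(lab)
        return tuple(seen)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.labels_F + self.labels_P

    @property
    def q(self) -> int:
        return len(self.labels_F)

    @property
    def p(self) -> int:
        return len(self.labels_P)

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((s, t) for s, t, _ in self.directed_edges)
        return list(nx.topological_sort(g))

    def make_theta(self, values: dict[str, float]) -> "ParameterVector":
        """Assemble a ParameterVector from a label -> value mapping."""
        try:
            vals = [float(values[lab]) for lab in self.labels]
        except KeyError as exc:
            raise ModelError(f"missing value for label {exc.args[0]!r}") from None
        return ParameterVector(self.labels_F, self.labels_P, np.asarray(vals))


@dataclass(frozen=True)
class ParameterVector:
    """Ordered theta = (theta_F, theta_P) with values in label order."""

    labels_F: tuple[str, ...]
    labels_P: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels_F", tuple(self.labels_F))
        object.__setattr__(self, "labels_P", tuple(self.labels_P))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if set(self.labels_F) & set(self.labels_P):
            raise ModelError("theta_F and theta_P labels must be disjoint")
        if self.values.shape != (len(self.labels_F) + len(self.labels_P),):
            raise ModelError("theta length does not match number of labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.labels_F + self.labels_P

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))

    def replace_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(self.labels_F, self.labels_P, values)


@dataclass(frozen=True)
class StructuralMatrices:
    """Numeric (C, Psi) pair for one value of theta."""

    C: np.ndarray
    Psi: np.ndarray

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class DerivativeStructure:
    """Constant Jacobians d vec(C)/d theta' and d vec(Psi)/d theta'.

    Both matrices are 0/1 incidence patterns (an off-diagonal covariance
    label sets the two symmetric vec positions, each with entry 1); they are
    constant because C and Psi are linear in theta.
    """

    dvecC: np.ndarray
    dvecPsi: np.ndarray


def _value_of(label: str, spec: ModelSpec, theta: ParameterVector) -> float:
    if label in spec.fixed_values:
        return float(spec.fixed_values[label])
    mapping = theta.as_dict()
    if label not in mapping:
        raise ModelError(f"no value supplied for label {label!r}")
    return mapping[label]


def build_matrices(spec: ModelSpec, theta: ParameterVector) -> StructuralMatrices:
    """Populate C(theta_F) and Psi(theta_P) from the symbolic spec.

    Shared labels produce identical entries at every tagged position.
    Raises :class:`ModelError` if Psi is not positive definite (smallest
    Cholesky pivot below 1e-10).
    """
    n = spec.n
    idx = {v: i for i, v in enumerate(spec.variables)}
    C = np.zeros((n, n))
    for s, t, lab in spec.directed_edges:
        C[idx[t], idx[s]] = _value_of(lab, spec, theta)
    Psi = np.zeros((n, n))
    for a, b, lab in spec.bidirected_edges:
        val = _value_of(lab, spec, theta)
        Psi[idx[a], idx[b]] = val
        Psi[idx[b], idx[a]] = val
    try:
        chol = np.linalg.cholesky(Psi)
    except np.linalg.LinAlgError:
        raise ModelError("Psi is not positive definite") from None
    if np.min(np.diag(chol)) ** 2 < _PD_TOL:
        raise ModelError("Psi is not positive definite (pivot below tolerance)")
    return StructuralMatrices(C=C, Psi=Psi)


def model_implied_covariance(mats: StructuralMatrices) -> np.ndarray:
    """Sigma = (I - C)^{-1} Psi (I - C)^{-T}, the reduced-form covariance."""
    n = mats.n
    b = np.linalg.solve(np.eye(n) - mats.C, np.eye(n))
    sigma = b @ mats.Psi @ b.T
    return 0.5 * (sigma + sigma.T)


def derivative_structure(spec: ModelSpec) -> DerivativeStructure:
    """Constant incidence Jacobians of vec(C) and vec(Psi) in theta.

    Columns follow theta order (structural labels then covariance labels);
    fixed labels contribute no column.  Exact by linearity:
    vec(C(theta + d)) - vec(C(theta)) = dvecC @ d.
    """
    n = spec.n
    idx = {v: i for i, v in enumerate(spec.variables)}
    labels = spec.labels
    col = {lab: k for k, lab in enumerate(labels)}
    dC = np.zeros((n * n, len(labels)))
    for s, t, lab in spec.directed_edges:
        if lab in col:
            dC[idx[s] * n + idx[t], col[lab]] = 1.0  # column-major vec position of (t, s)
    dP = np.zeros((n * n, len(labels)))
    for a, b, lab in spec.bidirected_edges:
        if lab in col:
            i, j = idx[a], idx[b]
            dP[j * n + i, col[lab]] = 1.0
            if i != j:
                dP[i * n + j, col[lab]] = 1.0
    return DerivativeStructure(dvecC=dC, dvecPsi=dP)


def extract_theta(spec: ModelSpec, mats: StructuralMatrices) -> ParameterVector:
    """Read label values back off numeric (C, Psi); inverse of build_matrices."""
    idx = {v: i for i, v in enumerate(spec.variables)}
    values: dict[str, float] = {}
    for s, t, lab in spec.directed_edges:
        values[lab] = mats.C[idx[t], idx[s]]
    for a, b, lab in spec.bidirected_edges:
        values[lab] = mats.Psi[idx[a], idx[b]]
    return spec.make_theta(values)


# ---------------------------------------------------------------------------
# spec file I/O


def load_spec(path: str) -> ModelSpec:
    """Read a model spec from YAML or JSON.

    Expected keys: ``variables`` (list of names), ``directed`` and
    ``bidirected`` (lists of 3-element entries ``[from, to, label]`` /
    ``[v1, v2, label]``) and optionally ``fixed`` (label -> value map).
    """
    with open(path) as fh:
        text = fh.read()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ModelError("model spec file must contain a mapping")
    for key in ("variables", "directed", "bidirected"):
        if key not in payload:
            raise ModelError(f"model spec missing key {key!r}")
    return ModelSpec(
        variables=tuple(payload["variables"]),
        directed_edges=tuple(tuple(e) for e in payload["directed"]),
        bidirected_edges=tuple(tuple(e) for e in payload["bidirected"]),
        fixed_values={k: float(v) for k, v in (payload.get("fixed") or {}).items()},
    )
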