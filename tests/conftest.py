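"""Shared fixtures: the insulin-glucose panel model, randomized recursive
models, and a central finite-difference oracle for Jacobian checks."""

import numpy as np
import pytest

from dosem import ModelSpec, illustration_fixture


@pytest.fixture(scope="session")
def panel():
    """(spec, population theta) of the packaged 6-variable panel model."""
    return illustration_fixture()


@pytest.fixture(scope="session")
def panel_spec(panel):
    return panel[0]


@pytest.fixture(scope="session")
def panel_theta(panel):
    return panel[1]


def random_recursive_model(rng: np.random.Generator, n: int, edge_prob: float = 0.5):
    """A random recursive model with all-distinct labels and PD errors.

    Directed edges go only from earlier to later variables (so C is
    strictly lower triangular in the given order); the error covariance is
    diagonally dominant to guarantee positive definiteness.
    """
    names = tuple(f"V{i+1}" for i in range(n))
    directed = []
    for j in range(1, n):
        for i in range(j):
            if rng.uniform() < edge_prob:
                directed.append((names[i], names[j], f"c_{j+1}{i+1}"))
    bidirected = [(names[i], names[i], f"p_{i+1}{i+1}") for i in range(n)]
    values = {}
    for _, _, lab in directed:
        values[lab] = float(rng.uniform(-0.9, 0.9))
    for i in range(n):
        values[f"p_{i+1}{i+1}"] = float(rng.uniform(1.0, 3.0))
    # a few bidirected edges, kept small against the variances
    for j in range(1, n):
        for i in range(j):
            if rng.uniform() < 0.25:
                lab = f"p_{j+1}{i+1}"
                bidirected.append((names[i], names[j], lab))
                values[lab] = float(rng.uniform(-0.3, 0.3))
    spec = ModelSpec(variables=names, directed_edges=tuple(directed),
                     bidirected_edges=tuple(bidirected))
    return spec, spec.make_theta(values)


@pytest.fixture(scope="session")
def panel_mc_500(panel):
    """Monte-Carlo replications of simulate -> ML fit -> delta method.

    2000 replications of the panel model at N=500 under do(X2 = 11.54),
    collecting the plug-in causal quantities and their 95% CIs; shared by
    the CI-coverage and asymptotic-variance checks.
    """
    import dosem as d
    from dosem.matops import vech_index

    spec, theta = panel
    system = d.CausalEffectSystem(spec, ("X2",), outcome="Y3")
    x = [11.54]
    y3 = spec.index("Y3")
    k_var = vech_index(y3, y3, spec.n)
    n_obs, nrep = 500, 2000
    rows = []
    for r in range(nrep):
        data = d.simulate_observational(spec, theta, n_obs, seed=50_000 + r)
        res = d.ml_fit(spec, d.sample_moments(data, spec), n_starts=1)
        cq1 = system.with_asymptotics(
            system.quantity("mean", res.theta_hat, x=x), res.av_theta, n_obs
        )
        cq4 = system.with_asymptotics(
            system.quantity("interval-probability", res.theta_hat, x=x, y_low=-40.0, y_up=80.0),
            res.av_theta,
            n_obs,
        )
        rows.append(
            (
                cq1.ci95[y3, 0], cq1.ci95[y3, 1],
                cq4.ci95[0, 0], cq4.ci95[0, 1],
                system.g2(res.theta_hat)[k_var],
            )
        )
    arr = np.asarray(rows)
    truth = {
        "g1": float(system.g1(theta, x)[y3]),
        "g4": float(system.g4(theta, x, -40.0, 80.0)),
        "g2": float(system.g2(theta)[k_var]),
    }
    return {
        "N": n_obs,
        "ci1": arr[:, 0:2],
        "ci4": arr[:, 2:4],
        "g2_hat": arr[:, 4],
        "truth": truth,
        "spec": spec,
        "theta": theta,
        "system": system,
    }


def finite_difference_jacobian(func, theta, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite differences of func(theta) over every free parameter."""
    v0 = theta.values
    cols = []
    for i in range(v0.size):
        h = rel_step * max(1.0, abs(v0[i]))
        vp, vm = v0.copy(), v0.copy()
        vp[i] += h
        vm[i] -= h
        fp = np.atleast_1d(func(theta.replace_values(vp)))
        fm = np.atleast_1d(func(theta.replace_values(vm)))
        cols.append((fp - fm) / (2.0 * h))
    return np.stack(cols, axis=-1)
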