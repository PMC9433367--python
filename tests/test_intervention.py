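"""Do-operator: selection/transformation matrices, interventional moments,
densities, interval probabilities, ATEs and optimal treatment levels."""

import numpy as np
import pytest
from scipy import integrate, stats

from dosem import (
    FlatObjectiveError,
    GaussianQuery,
    Intervention,
    ModelSpec,
    average_treatment_effect,
    build_matrices,
    conditional_distribution,
    interval_probability,
    interventional_moments,
    interventional_pdf,
    marginal_interventional,
    model_implied_covariance,
    optimal_intervention_level,
    optimal_intervention_for_model,
    selection_matrices,
    success_probability,
    transformation_matrices,
)
from conftest import random_recursive_model

X2 = 11.54  # one population standard deviation of insulin at t=2


@pytest.fixture(scope="module")
def panel_do_x2(panel):
    spec, theta = panel
    mats = build_matrices(spec, theta)
    iv = Intervention.from_names(spec, {"X2": X2})
    sel = selection_matrices(spec.n, iv)
    dist = interventional_moments(mats, sel, iv)
    return spec, theta, mats, iv, sel, dist


class TestSelectionMatrices:
    def test_single_do_variable_in_six(self):
        iv = Intervention(n=6, index_set=(3,), levels=[0.0])
        sel = selection_matrices(6, iv)
        assert np.array_equal(sel.one_I.ravel(), np.eye(6)[:, 2])
        assert np.array_equal(np.diag(sel.I_N), [1, 1, 0, 1, 1, 1])
        assert np.array_equal(sel.one_I.T @ sel.one_I, np.eye(1))
        assert np.array_equal(sel.one_N @ sel.one_N.T, sel.I_N)

    def test_empty_intervention_is_observational(self):
        iv = Intervention(n=4, index_set=(), levels=[])
        sel = selection_matrices(4, iv)
        assert np.array_equal(sel.one_N, np.eye(4))
        assert np.array_equal(sel.I_N, np.eye(4))

    def test_two_of_three(self):
        iv = Intervention(n=3, index_set=(1, 3), levels=[0.0, 0.0])
        sel = selection_matrices(3, iv)
        assert np.array_equal(sel.one_N.ravel(), np.eye(3)[:, 1])
        assert np.array_equal(np.diag(sel.I_N), [0, 1, 0])

    def test_out_of_range_and_duplicates_rejected(self):
        with pytest.raises(ValueError):
            Intervention(n=3, index_set=(0,), levels=[1.0])
        with pytest.raises(ValueError):
            Intervention(n=3, index_set=(2, 2), levels=[1.0, 1.0])


class TestTransformationMatrices:
    def test_panel_a1_carries_direct_effects(self, panel_do_x2):
        spec, theta, mats, iv, sel, _ = panel_do_x2
        _, a1, _, _ = transformation_matrices(mats, sel)
        assert np.allclose(a1.ravel(), [0, 0, 1, 0, 0.05, -0.6], atol=1e-12)

    def test_no_pathways_limit(self):
        spec = ModelSpec(("A", "B"), (), (("A", "A", "va"), ("B", "B", "vb")))
        mats = build_matrices(spec, spec.make_theta({"va": 1.0, "vb": 1.0}))
        iv = Intervention(n=2, index_set=(1,), levels=[0.0])
        sel = selection_matrices(2, iv)
        t1, a1, _, _ = transformation_matrices(mats, sel)
        assert np.array_equal(t1, sel.I_N)
        assert np.array_equal(a1, sel.one_I)

    @pytest.mark.parametrize("seed", range(8))
    def test_rank_reduction_on_random_models(self, seed):
        """T1 has rank n-K_x and T2 full row rank n-K_x."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        spec, theta = random_recursive_model(rng, n=n)
        mats = build_matrices(spec, theta)
        k = int(rng.integers(1, n))
        idx = tuple(sorted(rng.choice(np.arange(1, n + 1), size=k, replace=False)))
        sel = selection_matrices(n, Intervention(n=n, index_set=idx, levels=np.zeros(k)))
        t1, _, t2, _ = transformation_matrices(mats, sel)
        assert np.linalg.matrix_rank(t1) == n - k
        assert np.linalg.matrix_rank(t2) == n - k


class TestInterventionalMoments:
    def test_panel_population_variance_and_mean(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        y3 = spec.index("Y3")
        assert dist.covariance[y3, y3] == pytest.approx(1096.3855, abs=1e-4)
        assert dist.mean[y3] == pytest.approx(-6.92, abs=5e-3)
        assert dist.rank == 5

    def test_do_rows_and_columns_exactly_zero(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        x2 = spec.index("X2")
        assert np.all(dist.covariance[x2, :] == 0.0)
        assert np.all(dist.covariance[:, x2] == 0.0)
        assert dist.mean[x2] == X2

    def test_observational_limit(self, panel):
        spec, theta = panel
        mats = build_matrices(spec, theta)
        iv = Intervention(n=spec.n, index_set=(), levels=[])
        dist = interventional_moments(mats, selection_matrices(spec.n, iv), iv)
        assert np.allclose(dist.mean, 0.0)
        assert np.allclose(dist.covariance, model_implied_covariance(mats), atol=1e-10)

    def test_covariance_independent_of_level(self, panel):
        spec, theta = panel
        mats = build_matrices(spec, theta)
        covs = []
        for x in (-25.0, 0.0, 40.0):
            iv = Intervention.from_names(spec, {"X2": x})
            covs.append(interventional_moments(mats, selection_matrices(spec.n, iv), iv).covariance)
        assert np.array_equal(covs[0], covs[1])
        assert np.array_equal(covs[1], covs[2])


class TestMarginals:
    def test_univariate_outcome_moments(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        mu, cov = marginal_interventional(dist, GaussianQuery.from_names(spec, "Y3"))
        assert mu[0] == pytest.approx(-0.6 * X2, abs=1e-10)
        assert cov[0, 0] == pytest.approx(1096.3855, abs=1e-4)

    def test_all_of_N_matches_T2_form(self, panel_do_x2):
        spec, _, mats, iv, sel, dist = panel_do_x2
        query = GaussianQuery(iv.complement)
        mu, cov = marginal_interventional(dist, query)
        _, _, t2, a2 = transformation_matrices(mats, sel)
        assert np.allclose(mu, a2 @ iv.levels, atol=1e-12)
        assert np.allclose(cov, t2 @ mats.Psi @ t2.T, atol=1e-10)

    def test_querying_do_variable_rejected(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        with pytest.raises(ValueError, match="interventional"):
            marginal_interventional(dist, GaussianQuery.from_names(spec, "X2"))

    def test_bivariate_marginal_matches_simulation(self, panel):
        from dosem import simulate_interventional

        spec, theta = panel
        mats = build_matrices(spec, theta)
        iv = Intervention.from_names(spec, {"X2": X2})
        dist = interventional_moments(mats, selection_matrices(spec.n, iv), iv)
        q = GaussianQuery.from_names(spec, ["X3", "Y3"])
        mu, cov = marginal_interventional(dist, q)
        n_draws = 200_000
        draws = simulate_interventional(spec, theta, iv, n_draws, seed=42)
        emp = draws[["X3", "Y3"]].to_numpy()
        emp_cov = np.cov(emp, rowvar=False)
        # 3 SEs on each covariance entry (normal theory: SE ~ sqrt((s_ii s_jj + s_ij^2)/n))
        for i in range(2):
            for j in range(2):
                se = np.sqrt((cov[i, i] * cov[j, j] + cov[i, j] ** 2) / n_draws)
                assert abs(emp_cov[i, j] - cov[i, j]) < 3 * se


class TestDensity:
    def test_estimate_row_density_at_zero(self):
        """Printed N=100 estimates as inputs: density of glucose at 0."""
        dens = stats.norm.pdf(0.0, loc=-0.5217 * X2, scale=np.sqrt(1007.2180))
        assert dens == pytest.approx(0.0123, abs=5e-5)

    def test_density_at_mode(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        q = GaussianQuery.from_names(spec, "Y3")
        mu, cov = marginal_interventional(dist, q)
        assert interventional_pdf(dist, q, mu) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi * cov[0, 0]), rel=1e-12
        )

    def test_density_integrates_to_one(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        q = GaussianQuery.from_names(spec, "Y3")
        val, _ = integrate.quad(lambda y: interventional_pdf(dist, q, [y]), -500, 500)
        assert val == pytest.approx(1.0, abs=1e-8)


class TestIntervalProbability:
    def test_population_success_probability(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        q = GaussianQuery.from_names(spec, "Y3", [-40.0], [80.0])
        assert interval_probability(dist, q) == pytest.approx(0.8368, abs=5e-5)

    def test_unbounded_interval_is_one(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        q = GaussianQuery.from_names(spec, "Y3", [-np.inf], [np.inf])
        assert interval_probability(dist, q) == pytest.approx(1.0, abs=1e-12)

    def test_estimate_row_success_probability(self):
        assert success_probability(-0.5217, 1007.2180, X2, -40.0, 80.0) == pytest.approx(
            0.8545, abs=5e-5
        )

    def test_monotone_in_bounds(self, panel_do_x2):
        spec, _, _, _, _, dist = panel_do_x2
        ups = np.linspace(-20, 120, 15)
        probs = [
            interval_probability(dist, GaussianQuery.from_names(spec, "Y3", [-40.0], [u]))
            for u in ups
        ]
        assert np.all(np.diff(probs) >= 0)
        lows = np.linspace(-80, 40, 15)
        probs = [
            interval_probability(dist, GaussianQuery.from_names(spec, "Y3", [lo], [80.0]))
            for lo in lows
        ]
        assert np.all(np.diff(probs) <= 0)

    def test_bivariate_rectangle_against_univariate_product(self, panel):
        # under do(X2), X3 and Y3 are correlated; compare the 2-d rectangle
        # probability against dense numerical integration
        spec, theta = panel
        mats = build_matrices(spec, theta)
        iv = Intervention.from_names(spec, {"X2": X2})
        dist = interventional_moments(mats, selection_matrices(spec.n, iv), iv)
        q = GaussianQuery.from_names(spec, ["X3", "Y3"], [-10.0, -40.0], [10.0, 80.0])
        p = interval_probability(dist, q)
        mu, cov = marginal_interventional(dist, GaussianQuery.from_names(spec, ["X3", "Y3"]))
        rv = stats.multivariate_normal(mean=mu, cov=cov)
        grid_x = np.linspace(-10, 10, 201)
        grid_y = np.linspace(-40, 80, 201)
        xx, yy = np.meshgrid(grid_x, grid_y, indexing="ij")
        dens = rv.pdf(np.stack([xx, yy], axis=-1))
        ref = np.trapezoid(np.trapezoid(dens, grid_y, axis=1), grid_x)
        assert p == pytest.approx(ref, abs=1e-4)


class TestATE:
    def test_panel_ate_is_lagged_coefficient(self, panel):
        spec, theta = panel
        mats = build_matrices(spec, theta)
        y3, x2 = spec.index("Y3") + 1, spec.index("X2") + 1
        assert average_treatment_effect(mats, y3, x2, 1.0, 0.0) == pytest.approx(-0.6)
        assert average_treatment_effect(mats, y3, x2, 5.0, 2.0) == pytest.approx(-0.6 * 3)

    def test_equal_levels_give_zero(self, panel):
        spec, theta = panel
        mats = build_matrices(spec, theta)
        assert average_treatment_effect(mats, 6, 3, 7.0, 7.0) == 0.0

    def test_chain_ate_is_product_of_path_coefficients(self):
        spec = ModelSpec(
            ("V1", "V2", "V3"),
            (("V1", "V2", "a"), ("V2", "V3", "b")),
            tuple((f"V{i}", f"V{i}", f"p{i}") for i in (1, 2, 3)),
        )
        theta = spec.make_theta({"a": 0.7, "b": -1.3, "p1": 1.0, "p2": 1.0, "p3": 1.0})
        mats = build_matrices(spec, theta)
        assert average_treatment_effect(mats, 3, 1, 1.0, 0.0) == pytest.approx(0.7 * -1.3)


class TestConditionalDistribution:
    def test_panel_seeing_vs_doing_contrast(self, panel):
        spec, theta = panel
        sigma = model_implied_covariance(build_matrices(spec, theta))
        y3, x2 = spec.index("Y3") + 1, spec.index("X2") + 1
        slopes, cov = conditional_distribution(sigma, (x2,), (y3,))
        assert slopes[0, 0] == pytest.approx(1.76, abs=5e-3)
        assert cov[0, 0] == pytest.approx(353.99, abs=5e-3)

    def test_empty_conditioning_is_marginal(self, panel):
        spec, theta = panel
        sigma = model_implied_covariance(build_matrices(spec, theta))
        _, cov = conditional_distribution(sigma, (), (spec.index("Y3") + 1,))
        assert cov[0, 0] == pytest.approx(766.91, abs=5e-3)

    def test_diagonal_sigma_gives_zero_slope(self):
        sigma = np.diag([2.0, 3.0, 4.0])
        slopes, cov = conditional_distribution(sigma, (1,), (3,))
        assert slopes[0, 0] == 0.0
        assert cov[0, 0] == 4.0


class TestOptimalIntervention:
    def test_estimate_row_optimum(self):
        x_star, p_star = optimal_intervention_level(-0.5217, 1007.2180, -40.0, 80.0)
        assert x_star == pytest.approx(-38.3, abs=0.05)
        assert p_star == pytest.approx(0.94, abs=5e-3)

    def test_population_slope_midpoint_closed_form(self):
        x_star, _ = optimal_intervention_level(-0.6, 1096.3855, -40.0, 80.0)
        assert x_star == pytest.approx(20.0 / -0.6, abs=1e-4)

    def test_symmetric_bounds_optimum_at_zero(self):
        for var in (10.0, 500.0):
            x_star, _ = optimal_intervention_level(0.8, var, -30.0, 30.0)
            assert x_star == pytest.approx(0.0, abs=1e-4)

    def test_zero_slope_flagged(self):
        with pytest.raises(FlatObjectiveError):
            optimal_intervention_level(0.0, 100.0, -40.0, 80.0)

    def test_model_route_matches_scalar_route(self, panel):
        spec, theta = panel
        mats = build_matrices(spec, theta)
        x_star, p_star = optimal_intervention_for_model(
            mats, spec.index("X2") + 1, spec.index("Y3") + 1, -40.0, 80.0
        )
        ref_x, ref_p = optimal_intervention_level(-0.6, 1096.3855360, -40.0, 80.0)
        assert x_star == pytest.approx(ref_x, abs=1e-6)
        assert p_star == pytest.approx(ref_p, abs=1e-10)
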