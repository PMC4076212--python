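import math

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from geoadd.core_io import RegionGraph
from geoadd.diagnostics import effective_sample_size, geweke_z
from geoadd.geoadditive import (
    MCMCConfig,
    _draw_gaussian_block,
    bspline_design,
    gibbs_sampler,
    icar_precision,
    load_draws,
    save_draws,
    spline_basis_at,
)
from geoadd.marginal import fit_logistic_irls
from geoadd.preprocess import build_analysis_set
from geoadd.synthetic import SimulationConfig, make_lattice_graph, simulate_survey


def _bernoulli_analysis(n1: int, n0: int) -> "object":
    n = n1 + n0
    df = pd.DataFrame({
        "id": [str(i) for i in range(n)],
        "age_respondent": np.full(n, 30),
        "bmi": np.concatenate([np.full(n1, 27.0), np.full(n0, 21.0)]),
    })
    return build_analysis_set(df, covariates=())


def _cox_de_boor(x: float, knots: np.ndarray, j: int, d: int) -> float:
    """Brute-force recursive B-spline basis evaluation (independent oracle)."""
    if d == 0:
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    left = 0.0
    if knots[j + d] != knots[j]:
        left = (x - knots[j]) / (knots[j + d] - knots[j]) * _cox_de_boor(x, knots, j, d - 1)
    right = 0.0
    if knots[j + d + 1] != knots[j + 1]:
        right = ((knots[j + d + 1] - x) / (knots[j + d + 1] - knots[j + 1])
                 * _cox_de_boor(x, knots, j + 1, d - 1))
    return left + right


class TestBsplineDesign:
    @pytest.mark.parametrize("k", [4, 10, 20])
    def test_partition_of_unity_including_endpoints(self, k):
        rng = np.random.default_rng(1)
        x = np.concatenate([[15.0, 49.0], rng.uniform(15, 49, 500)])
        block = bspline_design(x, k=k)
        np.testing.assert_allclose(block.basis.sum(axis=1), 1.0, atol=1e-12)

    def test_cubic_local_support(self):
        x = np.linspace(0, 1, 200)
        block = bspline_design(x, k=10)
        assert np.max((block.basis > 1e-12).sum(axis=1)) <= 4

    def test_matches_cox_de_boor_recursion(self):
        x = np.array([15.0, 22.3, 31.0, 44.9, 49.0])
        block = bspline_design(np.linspace(15, 49, 50), k=8)
        basis = spline_basis_at(x, block.knots, block.degree)
        for i, xi in enumerate(x):
            xi_eval = min(xi, 49.0 - 1e-9 * 49)  # closed right endpoint
            oracle = [_cox_de_boor(xi_eval, block.knots, j, 3) for j in range(8)]
            np.testing.assert_allclose(basis[i], oracle, atol=1e-10)

    def test_penalty_is_rw2_with_rank_k_minus_2(self):
        block = bspline_design(np.linspace(0, 1, 30), k=12)
        assert np.linalg.matrix_rank(block.penalty) == 10
        # second differences of a linear sequence are zero
        lin = np.arange(12.0)
        assert lin @ block.penalty @ lin == pytest.approx(0.0, abs=1e-20)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            bspline_design(np.full(10, 3.0), k=5)


class TestIcarPrecision:
    def test_path_graph_matrix(self):
        g = RegionGraph.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])
        np.testing.assert_array_equal(
            icar_precision(g),
            [[1.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 1.0]],
        )

    def test_cycle_graph_matrix(self):
        g = RegionGraph.from_edges(
            ["A", "B", "C", "D"],
            [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")],
        )
        q = icar_precision(g)
        assert np.all(np.diag(q) == 2.0)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rank_is_regions_minus_components(self, seed):
        rng = np.random.default_rng(seed)
        regions = [f"r{i}" for i in range(12)]
        edges = [(f"r{i}", f"r{j}") for i in range(12) for j in range(i + 1, 12)
                 if rng.random() < 0.15]
        g = RegionGraph.from_edges(regions, edges)
        q = icar_precision(g)
        assert np.linalg.matrix_rank(q) == g.n_regions - len(g.components)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)


class TestGaussianBlockDraw:
    def test_mean_and_covariance_match_dense_solver(self):
        rng = np.random.default_rng(42)
        b = rng.standard_normal((30, 3))
        omega = rng.uniform(0.1, 1.0, 30)
        prior = np.eye(3) * 0.5
        btwb = (b.T * omega) @ b
        rhs = b.T @ rng.standard_normal(30)
        m = btwb + prior
        expected_mean = np.linalg.solve(m, rhs)
        draws = np.array([
            _draw_gaussian_block(rng, btwb, rhs, prior) for _ in range(20_000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), expected_mean, atol=0.03)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(m), atol=0.03)


class TestGibbsSampler:
    def test_intercept_only_matches_grid_quadrature(self):
        # Bernoulli 7/10 with a diffuse N(0, 1e6) prior: the Gibbs posterior
        # mean and SD of the intercept must match 1-D quadrature within 0.02
        analysis = _bernoulli_analysis(7, 3)
        grid = np.linspace(-8, 8, 32_001)
        logpost = (7 * -np.log1p(np.exp(-grid)) + 3 * -np.log1p(np.exp(grid))
                   - grid**2 / (2 * 1e6))
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_q = float(np.sum(grid * w))
        sd_q = float(np.sqrt(np.sum((grid - mean_q) ** 2 * w)))

        config = MCMCConfig(iterations=22_000, burn_in=2_000, thinning=1, seed=9)
        draws = gibbs_sampler(analysis, covariates=(), smooths=(),
                              spatial=False, unstructured=False, config=config)
        b = draws.beta[:, 0]
        assert abs(b.mean() - mean_q) < 0.02
        assert abs(b.std() - sd_q) < 0.02

    def test_fixed_effects_posterior_matches_mle(self):
        # fixed-effects-only model, n=2,000, urban log-odds log(1.24):
        # posterior mean within 3 posterior SDs of the IRLS MLE per coefficient
        cfg = SimulationConfig(
            n_individuals=2000, beta={"residence[urban]": math.log(1.24)},
            f_age=lambda a: np.zeros_like(np.asarray(a, float)),
            f_page=lambda a: np.zeros_like(np.asarray(a, float)),
            tau2_spat=0.0, tau2_unstr=0.0, p_underweight=0.0, seed=31,
        )
        records, _ = simulate_survey(cfg)
        analysis = build_analysis_set(records)
        config = MCMCConfig(iterations=3000, burn_in=500, thinning=1, seed=12)
        draws = gibbs_sampler(analysis, covariates=("residence",), smooths=(),
                              spatial=False, unstructured=False, config=config)
        from geoadd.marginal import build_design
        from geoadd.core_io import default_codebook
        cb = default_codebook(tuple(analysis.data["state"].cat.categories))
        design = build_design(analysis, codebook=cb, covariates=("residence",),
                              include_age_groups=False)
        mle = fit_logistic_irls(design, analysis.y)
        for j, label in enumerate(draws.beta_labels):
            mean, sd = draws.beta[:, j].mean(), draws.beta[:, j].std()
            assert abs(mean - mle.coef[j]) < 3 * sd, label

    def test_same_seed_bit_identical_draws(self, lattice6):
        cfg = SimulationConfig(n_individuals=600, graph=lattice6, seed=3)
        records, _ = simulate_survey(cfg)
        analysis = build_analysis_set(records)
        config = MCMCConfig(iterations=80, burn_in=20, thinning=2, seed=17)
        d1 = gibbs_sampler(analysis, graph=lattice6, config=config)
        d2 = gibbs_sampler(analysis, graph=lattice6, config=config)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.u, d2.u)
        np.testing.assert_array_equal(d1.v, d2.v)
        for var in d1.spline_coefs:
            np.testing.assert_array_equal(d1.spline_coefs[var], d2.spline_coefs[var])

    def test_observed_region_missing_from_graph_errors(self, lattice6):
        cfg = SimulationConfig(n_individuals=200, graph=lattice6, seed=3)
        records, _ = simulate_survey(cfg)
        analysis = build_analysis_set(records)
        small = make_lattice_graph(2)  # lacks the observed regions
        with pytest.raises(ValueError, match="missing from graph"):
            gibbs_sampler(analysis, graph=small,
                          config=MCMCConfig(iterations=10, burn_in=0, thinning=1))

    def test_draws_round_trip_through_disk(self, tmp_path, recovery_run):
        draws = recovery_run["draws"]
        save_draws(draws, tmp_path / "d")
        back = load_draws(tmp_path / "d")
        np.testing.assert_allclose(back.beta, draws.beta)
        np.testing.assert_allclose(back.u, draws.u)
        assert back.beta_labels == draws.beta_labels
        assert back.regions == draws.regions


class TestRecoveryAndChainHealth:
    def test_sum_to_zero_constraints_every_saved_draw(self, recovery_run):
        draws = recovery_run["draws"]
        for comp in recovery_run["graph"].component_indices():
            np.testing.assert_allclose(
                draws.u[:, comp].sum(axis=1), 0.0, atol=1e-10
            )
        for var, block in draws.spline_blocks.items():
            fitted = draws.spline_coefs[var] @ block.basis.T  # S x n
            np.testing.assert_allclose(fitted.mean(axis=1), 0.0, atol=1e-10)

    def test_spatial_rank_correlation(self, recovery_run):
        assert recovery_run["report"]["spatial"]["rank_correlation"] >= 0.8

    def test_age_curve_peak_recovered(self, recovery_run):
        rep = recovery_run["report"]["age_respondent"]
        assert abs(rep["peak_posterior"] - 45.0) <= 5.0

    def test_beta_credible_regions_cover_truth(self, recovery_run):
        assert recovery_run["report"]["beta_coverage"] >= 0.8

    def test_effective_sample_size_and_geweke(self, recovery_run):
        draws = recovery_run["draws"]
        j = draws.beta_labels.index("(Intercept)")
        assert effective_sample_size(draws.beta[:, j]) > 100
        params = np.column_stack([draws.beta, draws.u, draws.v])
        zs = np.array([geweke_z(params[:, k]) for k in range(params.shape[1])])
        assert np.mean(np.abs(zs) < 3.0) >= 0.95

    def test_ess_agrees_with_arviz(self, recovery_run):
        az = pytest.importorskip("arviz")
        x = recovery_run["draws"].beta[:, 0]
        ours = effective_sample_size(x)
        ref = float(az.ess(x[None, :]))
        assert 0.5 * ref <= ours <= 2.0 * ref
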