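import json

import numpy as np
import pytest

from geoadd.geoadditive import MCMCConfig, PosteriorDraws, gibbs_sampler
from geoadd.preprocess import build_analysis_set
from geoadd.summaries import (
    categorize_map,
    export_map,
    format_or,
    nonlinear_curve,
    summarize_fixed,
)
from geoadd.synthetic import SimulationConfig, make_lattice_graph, simulate_survey


def _draws_from_arrays(beta, labels, u=None, v=None, regions=()):
    s = beta.shape[0]
    r = len(regions)
    return PosteriorDraws(
        beta=beta, beta_labels=labels, spline_coefs={}, spline_blocks={},
        u=u if u is not None else np.zeros((s, r)),
        v=v if v is not None else np.zeros((s, r)),
        regions=tuple(regions), tau2={}, config=MCMCConfig(iterations=2, burn_in=0,
                                                           thinning=1),
        reference_rows=["wealth[poorest]"],
    )


@pytest.fixture(scope="module")
def zero_truth_fit():
    """Full model fit to data whose true smooth and spatial effects are zero."""
    graph = make_lattice_graph(4)
    cfg = SimulationConfig(
        n_individuals=4000, graph=graph, beta={}, intercept=np.log(0.209 / 0.791),
        f_age=lambda a: np.zeros_like(np.asarray(a, float)),
        f_page=lambda a: np.zeros_like(np.asarray(a, float)),
        tau2_spat=0.0, tau2_unstr=0.0, p_underweight=0.0, seed=100,
    )
    records, truth = simulate_survey(cfg)
    analysis = build_analysis_set(records)
    config = MCMCConfig(iterations=1600, burn_in=400, thinning=2, seed=23)
    draws = gibbs_sampler(analysis, graph=graph, config=config,
                          covariates=("residence", "wealth"))
    return draws


class TestSummarizeFixed:
    def test_constant_draws_give_degenerate_cr(self):
        c = 0.3
        with pytest.warns(UserWarning, match="saved draws"):
            table = summarize_fixed(
                _draws_from_arrays(np.full((50, 2), [0.0, c]),
                                   ["(Intercept)", "residence[urban]"])
            )
        row = table[table.term == "residence[urban]"].iloc[0]
        assert row.por == pytest.approx(np.exp(c))
        assert row.cr_low == pytest.approx(np.exp(c))
        assert row.cr_high == pytest.approx(np.exp(c))

    def test_symmetric_draws_straddle_one(self, rng):
        beta = np.column_stack([np.zeros(4000), rng.standard_normal(4000) * 0.2])
        table = summarize_fixed(_draws_from_arrays(beta, ["(Intercept)", "x"]))
        row = table[table.term == "x"].iloc[0]
        assert row.por == pytest.approx(1.0, abs=0.05)
        assert row.cr_low < 1.0 < row.cr_high
        ref = table[table.reference].iloc[0]
        assert ref.term == "wealth[poorest]" and ref.por == 1.0

    def test_report_display_format(self):
        assert format_or(1.2401, 1.1449, 1.3599) == "1.24 (1.14, 1.36)"
        assert format_or(0.48, 0.36, 0.61) == "0.48 (0.36, 0.61)"
        assert format_or(2.32, 1.62, 3.40) == "2.32 (1.62, 3.40)"

    def test_mean_of_exp_flag(self, rng):
        beta = np.column_stack([np.zeros(2000), rng.standard_normal(2000)])
        t1 = summarize_fixed(_draws_from_arrays(beta, ["(Intercept)", "x"]))
        t2 = summarize_fixed(_draws_from_arrays(beta, ["(Intercept)", "x"]),
                             mean_of_exp=True)
        # E[exp(Z)] > exp(E[Z]) by Jensen
        assert t2.iloc[0].por > t1.iloc[0].por


class TestNonlinearCurve:
    def test_constant_coefficients_give_flat_zero_curve(self, recovery_run):
        draws = recovery_run["draws"]
        var = "age_respondent"
        frozen = PosteriorDraws(
            beta=draws.beta, beta_labels=draws.beta_labels,
            spline_coefs={var: np.full_like(draws.spline_coefs[var], 0.7)},
            spline_blocks=draws.spline_blocks, u=draws.u, v=draws.v,
            regions=draws.regions, tau2=draws.tau2, config=draws.config,
        )
        curve = nonlinear_curve(frozen, var)
        np.testing.assert_allclose(curve["posterior_mean"], 0.0, atol=1e-10)

    def test_band_covers_zero_truth(self, zero_truth_fit):
        curve = nonlinear_curve(zero_truth_fit, "age_respondent", level=0.80)
        frac = np.mean((curve.cr_low <= 0) & (0 <= curve.cr_high))
        assert frac >= 0.90

    def test_peak_location_recovered(self, recovery_run):
        curve = nonlinear_curve(recovery_run["draws"], "age_respondent",
                                grid=np.arange(15.0, 50.0))
        peak = curve["age_respondent"][curve["posterior_mean"].idxmax()]
        assert 40.0 <= peak <= 50.0

    def test_extrapolation_refused(self, recovery_run):
        with pytest.raises(ValueError, match="extrapolat"):
            nonlinear_curve(recovery_run["draws"], "age_respondent",
                            grid=np.array([5.0, 60.0]))


class TestCategorizeMap:
    def test_all_positive_draws_are_positive_category(self):
        u = np.abs(np.random.default_rng(0).standard_normal((500, 2))) + 0.1
        d = _draws_from_arrays(np.zeros((500, 1)), ["(Intercept)"],
                               u=u, v=np.zeros((500, 2)), regions=["A", "B"])
        table = categorize_map(d)
        assert (table.category == "positive").all()
        assert (table.por > 1).all()

    def test_symmetric_draws_are_none_category(self, rng):
        u = rng.standard_normal((2000, 2))
        d = _draws_from_arrays(np.zeros((2000, 1)), ["(Intercept)"],
                               u=u, v=np.zeros((2000, 2)), regions=["A", "B"])
        assert (categorize_map(d).category == "none").all()

    def test_widening_level_never_creates_significance(self, recovery_run):
        t80 = categorize_map(recovery_run["draws"], level=0.80)
        t95 = categorize_map(recovery_run["draws"], level=0.95)
        sig95 = set(t95.loc[t95.category != "none", "region"])
        sig80 = set(t80.loc[t80.category != "none", "region"])
        assert sig95 <= sig80

    def test_calibration_under_zero_truth(self, zero_truth_fit):
        table = categorize_map(zero_truth_fit, level=0.80)
        assert (table.category == "none").mean() >= 0.7

    def test_unobserved_region_flagged(self, rng):
        u = rng.standard_normal((300, 2)) * 0.1
        d = _draws_from_arrays(np.zeros((300, 1)), ["(Intercept)"],
                               u=u, v=np.zeros((300, 2)), regions=["A", "B"])
        with pytest.warns(UserWarning, match="without observations"):
            table = categorize_map(d, observed_regions={"A"})
        assert table.loc[table.region == "B", "prior_dominated"].item()


class TestExportMap:
    @staticmethod
    def _toy_geojson():
        square = [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]
        return {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"region": "A"},
                 "geometry": {"type": "Polygon", "coordinates": square}},
                {"type": "Feature", "properties": {"region": "B"},
                 "geometry": {"type": "Polygon", "coordinates": square}},
            ],
        }

    @staticmethod
    def _toy_table():
        import pandas as pd
        return pd.DataFrame({
            "region": ["A", "B"], "por": [1.5, 0.7],
            "cr_low": [1.1, 0.5], "cr_high": [2.0, 0.98],
            "category": ["positive", "negative"],
        })

    def test_features_gain_properties_and_round_trip(self, tmp_path):
        out = tmp_path / "map.geojson"
        export_map(self._toy_table(), self._toy_geojson(), out_path=out)
        back = json.loads(out.read_text())
        for feat in back["features"]:
            props = feat["properties"]
            assert {"por", "cr_low", "cr_high", "category"} <= set(props)
        a = back["features"][0]["properties"]
        assert a["por"] == 1.5 and a["category"] == "positive"

    def test_missing_polygon_is_named(self):
        geo = self._toy_geojson()
        geo["features"] = geo["features"][:1]
        with pytest.raises(ValueError, match="B"):
            export_map(self._toy_table(), geo)
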