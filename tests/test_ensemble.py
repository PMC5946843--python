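"""Ensemble engine: grid enumeration, candidate fits, exclusion rules,
pooling, the projection chain and random-walk noise."""

import itertools

import numpy as np
import pandas as pd
import pytest

from healthcast import DrawSet
from healthcast.ensemble import (
    CONVERGENCE,
    TARGETS,
    WEIGHT_SCHEMES,
    FittedCandidate,
    ModelSpec,
    add_random_walk_noise,
    allocate_draws,
    apply_exclusion_rules,
    build_model_grid,
    default_grid,
    fit_candidate,
    historical_growth_bounds,
    pooling_weights,
    project_chain,
    rank_and_pool,
    _design,
    _forecast_growth,
)
from healthcast.errors import ConfigError, FitError, PoolingError


def growth_panel(levels0, n_years, growth_fn, noise_sd=0.0, seed=0, education=None):
    """Panel whose log GDP per capita follows growth_t = growth_fn(level_{t-1})."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, lv0 in enumerate(levels0):
        lv = lv0
        for t in range(n_years):
            if t > 0:
                lv = lv + growth_fn(lv) + noise_sd * rng.standard_normal()
            rows.append(
                {
                    "country_id": f"G{i:02d}",
                    "year": 2000 + t,
                    "gdp_pc": np.exp(lv),
                    "gov_spend": 1e9,
                    "ghes_pc": 100.0,
                    "ppp_pc": 10.0,
                    "oop_pc": 30.0,
                    "dah_pc": 0.0,
                    "population": 1e6,
                    "uhc_index": 50.0,
                    "income_group": "low",
                    "super_region": "south_asia",
                    "frac_under20": 0.3,
                    "frac_over65": 0.1,
                    "education_years": 8.0 if education is None else education(rng),
                    "tfr": 3.0,
                }
            )
    return pd.DataFrame(rows)


def intercept_model(value, countries, rmse=1.0, target="gdp_growth"):
    """A degenerate candidate predicting a constant growth `value`."""
    return FittedCandidate(
        spec=ModelSpec(target=target, covariates=()),
        columns=["const"],
        coefficients=np.array([value]),
        cov_params=np.zeros((1, 1)),
        p_values=np.array([0.0]),
        convergence_coef=None,
        phi=np.zeros(0),
        theta=np.zeros(0),
        sigma2=0.0,
        oos_rmse=rmse,
        oos_sd_by_country=pd.Series(0.0, index=countries),
        pred_min=value,
        pred_max=value,
        last_level=pd.Series(0.0, index=countries),
        last_cov=pd.DataFrame(index=pd.Index(countries)),
    )


class TestGrid:
    def test_singleton_grid(self):
        grid = build_model_grid([("convergence_term",)], ["equal"], [0], [0], "gdp_growth")
        assert len(grid) == 1

    def test_product_count(self):
        grid = build_model_grid(
            [(), (CONVERGENCE,)], list(WEIGHT_SCHEMES), [0, 1, 2, 3], [0, 1, 2, 3],
            "gdp_growth",
        )
        assert len(grid) == 2 * 4 * 4 * 4

    def test_size_matches_brute_force_enumeration(self):
        subsets = [(), ("tfr",), ("tfr", CONVERGENCE)]
        weights, ars, mas = ["equal", "decay20"], [0, 2], [1, 3]
        grid = build_model_grid(subsets, weights, ars, mas, "oop_share_gdp")
        brute = {
            (s, w, p, q)
            for s, w, p, q in itertools.product(map(tuple, subsets), weights, ars, mas)
        }
        assert len(grid) == len(brute)
        assert {(m.covariates, m.weight_scheme, m.ar_order, m.ma_order) for m in grid} == brute

    def test_empty_dimension_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            build_model_grid([], ["equal"], [0], [0], "gdp_growth")

    def test_default_grid_documents_its_count(self):
        assert len(default_grid("gdp_growth")) == 16 * 4 * 4 * 4


class TestFitCandidate:
    def test_exact_convergence_fit(self):
        """growth = 4 - level_{t-1} exactly: slope -1, intercept 4, zero residuals."""
        panel = growth_panel([1.0, 2.0, 3.0, 2.5, 1.5], 4, lambda lv: 4.0 - lv)
        spec = ModelSpec(target="gdp_growth", covariates=(CONVERGENCE,))
        fit = fit_candidate(panel, spec, holdout_years=1)
        coef = dict(zip(fit.columns, fit.coefficients))
        assert coef["const"] == pytest.approx(4.0, abs=1e-8)
        assert coef[CONVERGENCE] == pytest.approx(-1.0, abs=1e-8)
        assert fit.oos_rmse == pytest.approx(0.0, abs=1e-8)

    def test_equal_weights_match_unweighted_ols(self):
        panel = growth_panel(
            [1.0, 2.0, 3.0, 4.0], 10, lambda lv: 0.1 - 0.02 * lv, noise_sd=0.05
        )
        spec = ModelSpec(target="gdp_growth", covariates=(CONVERGENCE,), weight_scheme="equal")
        fit = fit_candidate(panel, spec, holdout_years=2)
        frame, cols = _design(panel, spec)
        ols = np.linalg.lstsq(frame[cols].to_numpy(), frame["y"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, ols, atol=1e-10)

    def test_collinear_covariate_raises(self):
        panel = growth_panel([1.0, 2.0], 6, lambda lv: 0.02)  # education constant
        spec = ModelSpec(target="gdp_growth", covariates=("education_years",))
        with pytest.raises(FitError, match="collinear|rank"):
            fit_candidate(panel, spec, holdout_years=1)

    def test_single_model_reduces_to_plain_regression_forecast(self):
        """No AR/MA, equal weights: the engine is an iterated WLS forecast."""
        panel = growth_panel(
            [1.0, 2.0, 3.0], 12, lambda lv: 0.3 - 0.05 * lv, noise_sd=0.01
        )
        spec = ModelSpec(target="gdp_growth", covariates=(CONVERGENCE,))
        fit = fit_candidate(panel, spec, holdout_years=2)
        a, b = fit.coefficients
        path = _forecast_growth(fit, 5)
        for country in path.index:
            lv = fit.last_level.loc[country]
            expected = []
            for _ in range(5):
                g = a + b * lv
                expected.append(g)
                lv += g
            np.testing.assert_allclose(path.loc[country], expected, atol=1e-12)


class TestExclusionRules:
    def _candidate(self, pvals, conv, pred_range, countries=("A",)):
        cand = intercept_model(0.0, list(countries))
        cand.columns = ["const"] + [f"x{i}" for i in range(len(pvals))]
        cand.p_values = np.array([0.0] + list(pvals))
        cand.convergence_coef = conv
        cand.pred_min, cand.pred_max = pred_range
        return cand

    def test_nonsignificant_covariate_dropped(self):
        cand = self._candidate([0.2, 0.01], conv=-0.1, pred_range=(0.0, 0.01))
        _, report = apply_exclusion_rules([cand], (-1.0, 1.0))
        assert report["reason"].tolist() == ["p_value"]

    def test_positive_convergence_dropped(self):
        cand = self._candidate([0.05, 0.01], conv=+0.01, pred_range=(0.0, 0.01))
        _, report = apply_exclusion_rules([cand], (-1.0, 1.0))
        assert report["reason"].tolist() == ["convergence_sign"]

    def test_out_of_bounds_dropped_and_pass_retained(self):
        bad = self._candidate([0.05, 0.01], conv=-0.01, pred_range=(0.0, 2.0))
        good = self._candidate([0.05, 0.01], conv=-0.01, pred_range=(0.0, 0.5))
        retained, report = apply_exclusion_rules([bad, good], (-1.0, 1.0))
        assert report["reason"].tolist() == ["bounds", None]
        assert retained == [good]

    def test_first_violated_rule_is_primary(self):
        cand = self._candidate([0.5], conv=+1.0, pred_range=(5.0, 9.0))
        _, report = apply_exclusion_rules([cand], (-1.0, 1.0))
        assert report["reason"].tolist() == ["p_value"]

    def test_idempotent(self):
        cands = [
            self._candidate([0.05], conv=-0.01, pred_range=(0.0, 0.5)),
            self._candidate([0.5], conv=-0.01, pred_range=(0.0, 0.5)),
        ]
        once, _ = apply_exclusion_rules(cands, (-1.0, 1.0))
        twice, report = apply_exclusion_rules(once, (-1.0, 1.0))
        assert twice == once and report["retained"].all()

    def test_empty_retained_is_legal(self):
        cand = self._candidate([0.9], conv=-0.01, pred_range=(0.0, 0.5))
        retained, _ = apply_exclusion_rules([cand], (-1.0, 1.0))
        assert retained == []


class TestPooling:
    countries = ["A", "B"]

    def test_single_model_is_its_own_ensemble(self, world):
        m = intercept_model(0.02, self.countries)
        draws = rank_and_pool([m], world, 10, 2040, seed=1)
        assert np.allclose(draws.values(), 0.02)

    def test_two_point_models_pool_to_mixture_mean(self, world):
        ms = [intercept_model(1.0, self.countries), intercept_model(3.0, self.countries)]
        draws = rank_and_pool(ms, world, 100, 2017, seed=1)
        cell = draws.frame.iloc[0]
        assert cell.mean() == pytest.approx(2.0)
        assert cell.var() == pytest.approx(1.0, rel=0.03)  # mixture of points 1 and 3

    def test_three_model_mixture_moments_match_closed_form(self, world):
        values, rmses = [1.0, 2.0, 4.0], [1.0, 1.0, 2.0]
        ms = [intercept_model(v, self.countries, rmse=r) for v, r in zip(values, rmses)]
        n = 100
        draws = rank_and_pool(ms, world, n, 2017, seed=1)
        counts = allocate_draws(pooling_weights(ms), n)
        # closed-form moments of the realised mixture of point masses
        vals = np.array(values)[np.argsort([m.spec.stable_hash() for m in ms], kind="stable")]
        mean = np.sum(counts * vals) / n
        var = np.sum(counts * vals**2) / n - mean**2
        cell = draws.frame.iloc[0]
        assert cell.mean() == pytest.approx(mean, abs=1e-12)
        assert cell.var(ddof=0) == pytest.approx(var, abs=1e-12)

    def test_mean_invariant_under_model_permutation(self, world):
        ms = [intercept_model(v, self.countries, rmse=r)
              for v, r in zip([1.0, 2.0, 4.0], [1.0, 0.5, 2.0])]
        a = rank_and_pool(ms, world, 100, 2020, seed=5).mean()
        b = rank_and_pool(ms[::-1], world, 100, 2020, seed=5).mean()
        pd.testing.assert_series_equal(a, b)

    def test_empty_retained_raises_pooling_error(self, world):
        with pytest.raises(PoolingError, match="fall back"):
            rank_and_pool([], world, 10, 2040)

    def test_largest_remainder_allocation(self):
        counts = allocate_draws(np.array([0.5, 0.3, 0.2]), 7)
        assert counts.sum() == 7
        assert counts.tolist() == [4, 2, 1]


class TestProjectChain:
    def _const_draws(self, panel, gdp_growth, horizon=2020, n_draws=5, share_diffs=None):
        countries = sorted(panel["country_id"].unique())
        last = int(panel["year"].max())
        years = list(range(last + 1, horizon + 1))
        shape = (len(countries), len(years), n_draws)
        draws = {"gdp_growth": DrawSet.from_array(
            np.full(shape, gdp_growth), countries, years, "gdp_growth")}
        for t in TARGETS[1:]:
            d = 0.0 if share_diffs is None else share_diffs.get(t, 0.0)
            draws[t] = DrawSet.from_array(np.full(shape, d), countries, years, t)
        return draws

    def test_constant_shares_propagate_gdp_growth(self, tiny_panel):
        draws = self._const_draws(tiny_panel, gdp_growth=0.02)
        lv = project_chain(tiny_panel, draws, 2020)
        for q in ["gdp_pc", "ghes_pc", "ppp_pc", "oop_pc", "total_pc"]:
            arr, _, _ = lv.array(q)
            ratio = arr[:, 1:, :] / arr[:, :-1, :]
            np.testing.assert_allclose(ratio, np.exp(0.02), rtol=1e-9)

    def test_ghes_share_shift_leaves_oop_unchanged(self, tiny_panel):
        base = self._const_draws(tiny_panel, gdp_growth=0.0)
        shifted = self._const_draws(tiny_panel, gdp_growth=0.0,
                                    share_diffs={"ghes_share_gov": 0.1})
        lv0 = project_chain(tiny_panel, base, 2020)
        lv1 = project_chain(tiny_panel, shifted, 2020)
        np.testing.assert_allclose(lv1.array("oop_pc")[0], lv0.array("oop_pc")[0])
        assert (lv1.array("ghes_pc")[0] > lv0.array("ghes_pc")[0]).all()

    def test_per_draw_identities_hold(self, world):
        rng = np.random.default_rng(9)
        countries = sorted(world["country_id"].unique())
        years = list(range(2016, 2021))
        draws = {
            t: DrawSet.from_array(
                rng.normal(0, 0.02, size=(len(countries), len(years), 100)),
                countries, years, t)
            for t in TARGETS
        }
        lv = project_chain(world, draws, 2020)
        total = lv.array("total_pc")[0]
        recomputed = sum(lv.array(q)[0] for q in ["ghes_pc", "ppp_pc", "oop_pc"])
        np.testing.assert_allclose(total, recomputed, rtol=1e-12)

    def test_horizon_before_last_year_rejected(self, tiny_panel):
        with pytest.raises(ConfigError):
            project_chain(tiny_panel, {}, 2000)


class TestRandomWalkNoise:
    def _zeros(self, n_years=4, n_draws=2000):
        return DrawSet.from_array(
            np.zeros((1, n_years, n_draws)), ["A"], list(range(2016, 2016 + n_years)),
            "gdp_growth")

    def test_zero_sd_is_identity(self):
        ds = self._zeros()
        out = add_random_walk_noise(ds, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_variance_grows_linearly_with_horizon(self):
        out = add_random_walk_noise(self._zeros(n_draws=20000), 1.0, seed=2)
        arr, _, _ = out.array("gdp_growth")
        var_by_year = arr[0].var(axis=1)
        np.testing.assert_allclose(var_by_year, [1, 2, 3, 4], rtol=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            add_random_walk_noise(self._zeros(), -1.0)

    def test_noisier_countries_get_wider_intervals(self):
        ds = DrawSet.from_array(np.zeros((2, 5, 4000)), ["A", "B"],
                                list(range(2016, 2021)), "gdp_growth")
        out = add_random_walk_noise(ds, pd.Series({"A": 0.1, "B": 0.5}), seed=3)
        arr, countries, _ = out.array("gdp_growth")
        width = np.percentile(arr, 97.5, axis=2) - np.percentile(arr, 2.5, axis=2)
        ia, ib = countries.index("A"), countries.index("B")
        assert (width[ib] > width[ia]).all()


def test_historical_bounds_cover_observed_growth(world):
    lo, hi = historical_growth_bounds(world)
    assert lo < hi
    wide = world.pivot(index="country_id", columns="year", values="gdp_pc")
    growth = np.diff(np.log(wide.to_numpy()), axis=1)
    assert lo == pytest.approx(growth.min()) and hi == pytest.approx(growth.max())
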