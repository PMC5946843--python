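"""Scenario construction: long-term growth, convergence regression,
residual-percentile alternatives, clipping and component scaling."""

import numpy as np
import pandas as pd
import pytest

from healthcast import (
    ScenarioSet,
    build_alternative_scenarios,
    clip_to_reference,
    compute_longterm_growth,
    fit_convergence_regression,
    scale_components,
)
from healthcast.errors import ComputationError, FitError
from healthcast.panel import total_spend_pc

from conftest import make_tiny_panel


def spending_panel(series_by_country: dict[str, list[float]], year0=1995):
    rows = []
    for c, series in series_by_country.items():
        for t, v in enumerate(series):
            rows.append({"country_id": c, "year": year0 + t, "ghes_pc": v,
                         "ppp_pc": 0.0, "oop_pc": 0.0, "dah_pc": 0.0})
    return pd.DataFrame(rows)


class TestLongtermGrowth:
    def test_doubling_over_20_years(self):
        series = list(np.linspace(100, 200, 21))
        p = spending_panel({"A": series})
        g = compute_longterm_growth(p)
        assert g["A"] == pytest.approx(np.log(2) / 20)

    def test_constant_series_zero_growth(self):
        p = spending_panel({"A": [50.0] * 10})
        assert compute_longterm_growth(p)["A"] == pytest.approx(0.0)

    def test_only_endpoints_matter(self):
        smooth = spending_panel({"A": list(np.linspace(100, 300, 11))})
        wild = spending_panel({"A": [100, 200, 100, 50, 400, 30, 90, 250, 70, 120, 300]})
        assert compute_longterm_growth(smooth)["A"] == compute_longterm_growth(wild)["A"]

    def test_nonpositive_endpoint_rejected(self):
        p = spending_panel({"A": [0.0] + [100.0] * 9})
        with pytest.raises(ComputationError, match="endpoint"):
            compute_longterm_growth(p)


class TestConvergenceRegression:
    def test_exact_linear_relation(self):
        x = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        y = 4.0 - x
        reg = fit_convergence_regression(y, x)
        assert reg.intercept == pytest.approx(4.0)
        assert reg.convergence_slope == pytest.approx(-1.0)
        np.testing.assert_allclose(reg.residuals, 0.0, atol=1e-12)

    def test_matches_normal_equations_on_five_points(self):
        x = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0, "E": 5.0})
        y = pd.Series({"A": 1.1, "B": 0.9, "C": 1.8, "D": 2.6, "E": 4.0})
        reg = fit_convergence_regression(y, x)
        # normal-equations oracle computed from scratch
        xa, ya = x.to_numpy(), y.to_numpy()
        n = len(xa)
        slope = (n * np.sum(xa * ya) - xa.sum() * ya.sum()) / (n * np.sum(xa**2) - xa.sum() ** 2)
        intercept = ya.mean() - slope * xa.mean()
        assert reg.convergence_slope == pytest.approx(slope, abs=1e-12)
        assert reg.intercept == pytest.approx(intercept, abs=1e-12)

    def test_shifting_y_moves_intercept_only(self):
        x = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0, "D": 4.0})
        y = pd.Series({"A": 1.0, "B": 1.5, "C": 2.5, "D": 3.0})
        r0 = fit_convergence_regression(y, x)
        r1 = fit_convergence_regression(y + 10.0, x)
        assert r1.intercept == pytest.approx(r0.intercept + 10.0)
        assert r1.convergence_slope == pytest.approx(r0.convergence_slope)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError, match="3 countries"):
            fit_convergence_regression(pd.Series({"A": 1.0}), pd.Series({"A": 1.0}))
        three = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(FitError, match="unidentifiable"):
            fit_convergence_regression(three, pd.Series({"A": 2.0, "B": 2.0, "C": 2.0}))


class TestAlternativeScenarios:
    def _reference(self, countries, years, level=100.0):
        rows = [{"country": c, "year": y, "reference": level} for c in countries for y in years]
        return pd.DataFrame(rows)

    def _fit_reg(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.Series(rng.uniform(3, 7, n), index=[f"C{i}" for i in range(n)])
        y = 0.05 - 0.004 * x + pd.Series(rng.normal(0, 0.01, n), index=x.index)
        return fit_convergence_regression(y, x)

    def test_zero_residuals_collapse_scenarios(self):
        x = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        reg = fit_convergence_regression(4.0 - x, x)  # exact fit, residuals 0
        ref = self._reference(["A", "B", "C"], [2016, 2017])
        baseline = pd.Series(100.0, index=["A", "B", "C"])
        with pytest.warns(UserWarning, match="degenerate"):
            scen = build_alternative_scenarios(reg, ref, baseline, 2015)
        np.testing.assert_allclose(scen.frame["better"], scen.frame["worse"])

    def test_residual_percentiles_use_type7_quantiles(self):
        reg = self._fit_reg()
        res = reg.residuals.to_numpy()
        rates = reg.scenario_growth()
        # direct order-statistic interpolation oracle
        np.testing.assert_allclose(
            (rates["better"] - reg.fitted).to_numpy(),
            np.quantile(res, 0.85, method="linear"),
        )
        np.testing.assert_allclose(
            (rates["worse"] - reg.fitted).to_numpy(),
            np.quantile(res, 0.15, method="linear"),
        )

    def test_better_growth_always_geq_worse(self):
        reg = self._fit_reg(seed=3)
        rates = reg.scenario_growth()
        assert (rates["better"] >= rates["worse"]).all()

    def test_paths_grow_from_baseline_at_constant_rates(self):
        reg = self._fit_reg(seed=4)
        countries = list(reg.fitted.index)
        ref = self._reference(countries, [2016, 2017, 2018])
        baseline = pd.Series(200.0, index=countries)
        scen = build_alternative_scenarios(reg, ref, baseline, 2015)
        rates = reg.scenario_growth()
        one = scen.frame[scen.frame["country"] == countries[0]].sort_values("year")
        g = rates.loc[countries[0], "better"]
        np.testing.assert_allclose(one["better"], 200.0 * np.exp(g * np.arange(1, 4)))


class TestClipping:
    def _scen(self, better, worse, reference=100.0):
        frame = pd.DataFrame({
            "country": "A", "year": [2016], "component": "total",
            "reference": [reference], "better": [better], "worse": [worse],
        })
        return ScenarioSet(frame)

    def test_better_below_reference_raised_to_reference(self):
        out = clip_to_reference(self._scen(better=90.0, worse=80.0))
        assert out.frame["better"].iloc[0] == 100.0

    def test_ordered_input_unchanged(self):
        scen = self._scen(better=120.0, worse=80.0)
        out = clip_to_reference(scen)
        pd.testing.assert_frame_equal(out.frame, scen.frame)

    def test_idempotent(self):
        scen = self._scen(better=90.0, worse=110.0)
        once = clip_to_reference(scen)
        twice = clip_to_reference(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        assert twice.is_ordered()


class TestScaleComponents:
    def _totals(self, ratio_better=1.1, ratio_worse=0.9):
        frame = pd.DataFrame({
            "country": "A", "year": [2016], "component": "total",
            "reference": [100.0], "better": [100.0 * ratio_better],
            "worse": [100.0 * ratio_worse],
        })
        return ScenarioSet(frame)

    def _components(self, values=(60.0, 30.0, 10.0)):
        return pd.DataFrame({
            "country": "A", "year": 2016,
            "component": ["ghes_pc", "oop_pc", "ppp_pc"],
            "reference": list(values),
        })

    def test_components_scale_proportionally(self):
        out = scale_components(self._totals(1.1), self._components())
        np.testing.assert_allclose(out.frame["better"], [66.0, 33.0, 11.0])

    def test_unit_ratio_is_identity(self):
        out = scale_components(self._totals(1.0, 1.0), self._components())
        np.testing.assert_allclose(out.frame["better"], out.frame["reference"])
        np.testing.assert_allclose(out.frame["worse"], out.frame["reference"])

    def test_component_sums_equal_scenario_totals_on_random_world(self):
        rng = np.random.default_rng(8)
        countries = [f"C{i:03d}" for i in range(188)]
        comp_rows, tot_rows = [], []
        for c in countries:
            parts = rng.uniform(1, 50, size=4)
            ratio_b, ratio_w = rng.uniform(1.0, 1.5), rng.uniform(0.5, 1.0)
            total = parts.sum()
            tot_rows.append({"country": c, "year": 2030, "component": "total",
                             "reference": total, "better": total * ratio_b,
                             "worse": total * ratio_w})
            for name, v in zip(["ghes_pc", "ppp_pc", "oop_pc", "dah_pc"], parts):
                comp_rows.append({"country": c, "year": 2030, "component": name,
                                  "reference": v})
        out = scale_components(ScenarioSet(pd.DataFrame(tot_rows)), pd.DataFrame(comp_rows))
        sums = out.frame.groupby(["country", "year"])[["reference", "better", "worse"]].sum()
        totals = pd.DataFrame(tot_rows).set_index(["country", "year"])
        for col in ("reference", "better", "worse"):
            np.testing.assert_allclose(sums[col], totals[col], rtol=1e-12)

    def test_mismatched_component_sum_rejected(self):
        comps = self._components((1.0, 2.0, 3.0))  # sums to 6, totals say 100
        with pytest.raises(ComputationError, match="sum"):
            scale_components(self._totals(), comps)
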