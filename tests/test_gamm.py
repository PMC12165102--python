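import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nutrigeom as ng
from nutrigeom.gamm_surface import (
    CountryPanel,
    GAMMSelectionError,
    OutOfRangeError,
    PanelDataError,
    PanelSchemaError,
    _build_design,
    make_knots,
)


# --- independent Cox-de Boor oracle ----------------------------------------


def cox_de_boor(x: float, j: int, k: int, t: np.ndarray) -> float:
    """Textbook B-spline recursion, written independently of scipy."""
    if k == 0:
        return 1.0 if t[j] <= x < t[j + 1] else 0.0
    left = 0.0
    if t[j + k] > t[j]:
        left = (x - t[j]) / (t[j + k] - t[j]) * cox_de_boor(x, j, k - 1, t)
    right = 0.0
    if t[j + k + 1] > t[j + 1]:
        right = (t[j + k + 1] - x) / (t[j + k + 1] - t[j + 1]) * cox_de_boor(x, j + 1, k - 1, t)
    return left + right


def _identity_panel(x, y, var="gdp"):
    """A minimal single-country panel carrying (x, y) for 1D smooth tests."""
    n = len(x)
    df = pd.DataFrame(
        {
            "country": "A",
            "year": np.arange(n) + 1900,
            "stratum": "both",
            "protein_kcal": 1.0,
            "carb_kcal": 1.0,
            "fat_kcal": 1.0,
            "gdp": np.exp(x),  # gdp enters the model as log(gdp) = x
            "rate": y,
        }
    )
    return CountryPanel(df)


class TestBsplineBasis:
    def test_matches_cox_de_boor_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 10.0, 100)
        n_basis, degree = 7, 3
        t = make_knots(0.0, 10.0, n_basis, degree)
        B = ng.bspline_basis(x, n_basis, degree, knots=t)
        expect = np.array(
            [[cox_de_boor(xi, j, degree, t) for j in range(n_basis)] for xi in x]
        )
        np.testing.assert_allclose(B, expect, atol=1e-10)

    @given(
        st.integers(min_value=4, max_value=12),
        st.integers(min_value=0, max_value=100),
    )
    def test_partition_of_unity(self, n_basis, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-3.0, 5.0, 40)
        B = ng.bspline_basis(x, n_basis)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_locality_at_left_boundary(self):
        x = np.array([0.0, 5.0, 10.0])
        B = ng.bspline_basis(x, 8, knots=make_knots(0, 10, 8))
        assert B[0, 0] > 0 and B[0, -1] == 0.0
        assert B[2, -1] > 0 and B[2, 0] == 0.0

    def test_out_of_range_raises(self):
        t = make_knots(0, 1, 5)
        with pytest.raises(OutOfRangeError):
            ng.bspline_basis(np.array([1.5]), 5, knots=t)

    def test_too_small_basis_rejected(self):
        with pytest.raises(ValueError, match="n_basis"):
            make_knots(0, 1, 3, degree=3)


class TestDifferencePenalty:
    def test_linear_vector_annihilated(self):
        S = ng.difference_penalty(5, order=2)
        beta = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert beta @ S @ beta == pytest.approx(0.0, abs=1e-12)

    def test_unit_vector_quadratic_form(self):
        S = ng.difference_penalty(5, order=2)
        e1 = np.array([1.0, 0, 0, 0, 0])
        assert e1 @ S @ e1 == pytest.approx(1.0)

    def test_equals_explicit_DtD(self):
        # independent construction: banded difference operator by hand
        n, order = 7, 2
        D = np.zeros((n - order, n))
        for i in range(n - order):
            D[i, i : i + 3] = [1.0, -2.0, 1.0]
        np.testing.assert_allclose(ng.difference_penalty(n, order), D.T @ D, atol=1e-12)

    def test_psd_and_null_space_dimension(self):
        S = ng.difference_penalty(8, order=2)
        w = np.linalg.eigvalsh(S)
        assert w.min() > -1e-12
        assert (np.abs(w) < 1e-10).sum() == 2  # constants and linear trends

    def test_order_must_be_below_basis(self):
        with pytest.raises(ValueError):
            ng.difference_penalty(2, order=2)


class TestTensorSmooth:
    def test_one_variable_reduces_to_centered_basis(self, small_panel):
        panel, _ = small_panel
        term = ng.SmoothTerm(("gdp",), basis_size=5)
        cols, pens, td = ng.tensor_smooth(term, panel)
        x = np.log(panel.data["gdp"].to_numpy())
        B = ng.bspline_basis(x, 5, knots=td.knots[0])
        np.testing.assert_allclose(cols, B - B.mean(axis=0), atol=1e-12)
        assert len(pens) == 1

    def test_two_variable_dimensions(self, small_panel):
        panel, _ = small_panel
        term = ng.SmoothTerm(("gdp", "year"), basis_size=3, degree=2)
        cols, pens, _ = ng.tensor_smooth(term, panel)
        assert cols.shape == (len(panel), 9)
        assert len(pens) == 2

    def test_columns_are_marginal_products(self, small_panel):
        panel, _ = small_panel
        term = ng.SmoothTerm(("gdp", "year"), basis_size=4)
        cols, _, td = ng.tensor_smooth(term, panel)
        pred = pd.DataFrame(
            {"gdp": np.log(panel.data["gdp"]), "year": panel.data["year"]}
        )
        Bg = ng.bspline_basis(pred["gdp"].to_numpy(), 4, knots=td.knots[0])
        By = ng.bspline_basis(pred["year"].to_numpy(), 4, knots=td.knots[1])
        rng = np.random.default_rng(0)
        rows = rng.integers(0, len(panel), 20)
        for i in rows:
            raw = np.kron(Bg[i], By[i])
            np.testing.assert_allclose(cols[i] + td.col_means, raw, atol=1e-12)


class TestFitGAMM:
    def test_large_lambda_gives_linear_fit(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 60))
        y = 1.0 + 0.7 * x + rng.normal(0, 0.3, 60)
        panel = _identity_panel(x, y - y.min() + 1.0)
        spec = ng.GAMMSpec(
            "s(gdp)", (ng.SmoothTerm(("gdp",), basis_size=8),),
            include_random_country=False, response_transform="identity",
        )
        fit = ng.fit_gamm(spec, panel, fixed_lambdas=1e8)
        yy = panel.data["rate"].to_numpy()
        line = np.polyval(np.polyfit(x, yy, 1), x)
        np.testing.assert_allclose(fit.fitted_values, line, atol=1e-4)
        assert fit.edf == pytest.approx(2.0, abs=1e-3)

    def test_zero_lambda_matches_ols_oracle(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 1, 30))
        y = np.sin(6 * x) + rng.normal(0, 0.1, 30)
        panel = _identity_panel(x, y - y.min() + 1.0)
        spec = ng.GAMMSpec(
            "s(gdp)", (ng.SmoothTerm(("gdp",), basis_size=10),),
            include_random_country=False, response_transform="identity",
        )
        fit = ng.fit_gamm(spec, panel, fixed_lambdas=0.0)
        X, _ = _build_design(spec, panel)
        yy = panel.data["rate"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        np.testing.assert_allclose(fit.fitted_values, X @ beta, atol=1e-8)

    def test_edf_decreases_with_lambda(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec(
            "s(gdp)", (ng.SmoothTerm(("gdp",), basis_size=8),), include_random_country=False
        )
        edfs = [
            ng.fit_gamm(spec, panel, fixed_lambdas=lam).edf
            for lam in (1e-3, 1e-1, 1e1, 1e3, 1e5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_gcv_rss_shrinks_with_basis_size_on_noiseless_data(self):
        x = np.linspace(0, 1, 80)
        y = np.sin(4 * x) + 2.0
        rss = []
        for K in (4, 8, 16):
            panel = _identity_panel(x, y)
            spec = ng.GAMMSpec(
                "s(gdp)", (ng.SmoothTerm(("gdp",), basis_size=K),),
                include_random_country=False, response_transform="identity",
            )
            rss.append(ng.fit_gamm(spec, panel).rss)
        assert rss[0] > rss[-1]
        assert rss[-1] < 1e-4

    def test_random_intercepts_shrunk_vs_raw_means(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec("N+Y", tuple(
            s for s in [ng.SmoothTerm(("protein", "carb", "fat"), basis_size=4),
                        ng.SmoothTerm(("year",), basis_size=5)]
        ))
        fit = ng.fit_gamm(spec, panel)
        u = fit.country_intercepts
        y = np.log(panel.data["rate"].to_numpy() + 0.5)
        resid = y - (fit.fitted_values - u[panel.data["country"]].to_numpy())
        raw_means = pd.Series(resid, index=panel.data["country"]).groupby(level=0).mean()
        assert u.var() < raw_means.var()

    def test_surface_recovery_on_synthetic_default(self, default_panel):
        panel, truth = default_panel
        spec = [s for s in ng.enumerate_candidates() if s.name == "NxG+Y"][0]
        fit = ng.fit_gamm(spec, panel)
        surf = ng.predict_nutrient_surface(fit, n_grid=25)
        F, C = np.meshgrid(surf.fat_grid, surf.carb_grid)
        tv = truth.surface(surf.protein_value, C, F, surf.gdp_value)
        m = surf.mask
        r = np.corrcoef(surf.values[m], tv[m])[0, 1]
        assert r >= 0.9

    def test_missing_stratum_errors(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(PanelDataError):
            panel.stratum("female")

    def test_schema_error_names_column(self):
        df = pd.DataFrame({"country": ["A"], "year": [2000]})
        with pytest.raises(PanelSchemaError, match="protein_kcal"):
            CountryPanel(df)


class TestCandidates:
    def test_ten_candidates_all_with_random_effect(self):
        cands = ng.enumerate_candidates()
        assert len(cands) == 10
        assert all(c.include_random_country for c in cands)

    def test_contains_favored_structure(self):
        names = [c.name for c in ng.enumerate_candidates()]
        assert "NxG+Y" in names

    def test_deterministic(self):
        a = [c.name for c in ng.enumerate_candidates()]
        b = [c.name for c in ng.enumerate_candidates()]
        assert a == b

    def test_selection_on_small_interaction_panel(self, small_panel):
        panel, _ = small_panel
        fit = ng.select_gamm(panel)
        assert fit.aic_table is not None
        assert len(fit.aic_table) == 10
        aics = fit.aic_table["aic"].to_numpy()
        assert np.all(np.diff(aics) >= 0)
        assert fit.aic == pytest.approx(aics[0])

    def test_all_failures_aggregate(self):
        empty = pd.DataFrame({c: pd.Series(dtype=object if c in ("country", "stratum") else float)
                              for c in ng.gamm_surface.PANEL_COLUMNS})
        with pytest.raises(GAMMSelectionError, match="all GAMM candidates failed"):
            ng.select_gamm(CountryPanel(empty))


class TestNutrientSurface:
    def test_null_spec_constant_surface(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec("null", (), include_random_country=True)
        fit = ng.fit_gamm(spec, panel)
        surf = ng.predict_nutrient_surface(fit, n_grid=15)
        vals = surf.values[surf.mask]
        np.testing.assert_allclose(vals, vals[0], atol=1e-10)

    def test_sign_pattern_recovered(self, default_panel):
        panel, _ = default_panel
        spec = [s for s in ng.enumerate_candidates() if s.name == "NxG+Y"][0]
        fit = ng.fit_gamm(spec, panel)
        surf = ng.predict_nutrient_surface(fit, n_grid=25)
        m = surf.mask
        dfat = np.diff(surf.values, axis=1)
        dcarb = np.diff(surf.values, axis=0)
        mf = m[:, 1:] & m[:, :-1]
        mc = m[1:, :] & m[:-1, :]
        frac = ((dfat[mf] < 0).sum() + (dcarb[mc] > 0).sum()) / (mf.sum() + mc.sum())
        assert frac >= 0.9

    def test_predictions_at_observations_match_fitted(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec("N", (ng.SmoothTerm(("protein", "carb", "fat"), basis_size=4),))
        fit = ng.fit_gamm(spec, panel)
        pred = ng.predict_gamm(fit, panel.data, use_country=True)
        np.testing.assert_allclose(pred, fit.fitted_values, atol=1e-8)

    def test_quantile_validated(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec("null", (), include_random_country=True)
        fit = ng.fit_gamm(spec, panel)
        with pytest.raises(ValueError, match="quantile"):
            ng.predict_nutrient_surface(fit, protein_quantile=1.2)

    def test_mask_inside_observed_hull(self, small_panel):
        panel, _ = small_panel
        spec = ng.GAMMSpec("null", (), include_random_country=True)
        fit = ng.fit_gamm(spec, panel)
        surf = ng.predict_nutrient_surface(fit, n_grid=15)
        F, C = np.meshgrid(surf.fat_grid, surf.carb_grid)
        m = surf.mask
        assert F[m].min() >= panel.data["fat_kcal"].min() - 1e-9
        assert C[m].max() <= panel.data["carb_kcal"].max() + 1e-9


class TestGeometry:
    def test_isocaloric_endpoints(self):
        seg = ng.isocaloric_line(2000.0, 300.0)
        np.testing.assert_allclose(seg, [[0, 1700], [1700, 0]])

    def test_isocaloric_slope_minus_one(self):
        seg = ng.isocaloric_line(2500.0, 400.0)
        slope = (seg[1, 1] - seg[0, 1]) / (seg[1, 0] - seg[0, 0])
        assert slope == pytest.approx(-1.0)

    def test_cf_ratio_decreases_along_line(self):
        seg = ng.isocaloric_line(2000.0, 300.0)
        f = np.linspace(1.0, seg[1, 0] - 1.0, 50)
        c = (seg[0, 1] + seg[1, 1]) - 0 - f  # c = E - f
        ratios = c / f
        assert np.all(np.diff(ratios) < 0)

    def test_invalid_isocaloric(self):
        with pytest.raises(ValueError):
            ng.isocaloric_line(200.0, 300.0)

    def test_radial_45_degrees(self):
        ray = ng.energy_radial(1.0, 2000.0)
        assert ray[1, 0] == pytest.approx(ray[1, 1])

    @given(st.floats(0.05, 20.0), st.floats(100.0, 5000.0))
    def test_radial_preserves_ratio(self, ratio, emax):
        ray = ng.energy_radial(ratio, emax)
        f = np.linspace(1e-6, ray[1, 0], 20)
        c = ratio * f
        np.testing.assert_allclose(c / f, ratio, atol=1e-12, rtol=1e-12)

    def test_radial_meets_isocaloric_once(self):
        seg = ng.isocaloric_line(2000.0, 300.0)
        E = seg[0, 1]
        ratio = 2.0
        f_star = E / (1 + ratio)  # unique intersection of c=rf with f+c=E
        assert 0 < f_star < E


class TestMgcvCrossCheck:
    def test_1d_smooth_agrees_with_mgcv(self, tmp_path):
        """Independent route: the same smoothing problem through R mgcv."""
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 1, 150))
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.2, 150)
        panel = _identity_panel(x, y - y.min() + 1.0)
        spec = ng.GAMMSpec(
            "s(gdp)", (ng.SmoothTerm(("gdp",), basis_size=10),),
            include_random_country=False, response_transform="identity",
        )
        fit = ng.fit_gamm(spec, panel)
        data = tmp_path / "d.csv"
        pd.DataFrame({"x": x, "y": panel.data["rate"]}).to_csv(data, index=False)
        out = tmp_path / "f.csv"
        script = (
            f"d <- read.csv('{data}'); library(mgcv);"
            f"m <- gam(y ~ s(x, bs='ps', k=10), data=d);"
            f"write.csv(data.frame(f=fitted(m)), '{out}', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        mg = pd.read_csv(out)["f"].to_numpy()
        r = np.corrcoef(fit.fitted_values, mg)[0, 1]
        assert r > 0.99
        assert np.abs(fit.fitted_values - mg).max() < 0.2  # both track the same curve
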