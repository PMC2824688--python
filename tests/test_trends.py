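"""Linear trend fitting and risk projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carpsim as cs
from carpsim.states import EventType, HistoryState
from carpsim.trends import TrendSurface


def closed_form_ols(xs, ys):
    """Independent closed-form least squares: slope and value at max(xs)."""
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    return slope, intercept + slope * x.max()


class TestFitLinearTrend:
    def test_collinear_points_recovered_exactly(self):
        tr = cs.fit_linear_trend([(1998, 0.10), (1999, 0.09), (2000, 0.08)])
        assert tr.slope == pytest.approx(-0.01, abs=1e-15)
        assert tr.level == pytest.approx(0.08, abs=1e-15)
        assert tr.reference_year == 2000

    def test_constant_series(self):
        tr = cs.fit_linear_trend([(1998, 0.05), (1999, 0.05), (2000, 0.05)])
        assert tr.slope == 0.0
        assert tr.level == pytest.approx(0.05)

    def test_non_collinear_matches_closed_form(self):
        obs = [(1998, 0.10), (1999, 0.10), (2000, 0.07)]
        tr = cs.fit_linear_trend(obs)
        slope, level = closed_form_ols(*zip(*obs[::-1]))  # order must not matter
        assert tr.slope == pytest.approx(-0.015, abs=1e-15)
        assert tr.slope == pytest.approx(slope, abs=1e-15)
        assert tr.level == pytest.approx(level, abs=1e-15)

    def test_missing_year_rejected(self):
        with pytest.raises(cs.DomainError, match="1999"):
            cs.fit_linear_trend([(1998, 0.1), (2000, 0.1)])

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(cs.DomainError):
            cs.fit_linear_trend([(1998, 0.1), (1999, 1.2), (2000, 0.1)])

    def test_endpoints_method(self):
        tr = cs.fit_linear_trend([(1998, 0.10), (1999, 0.20), (2000, 0.06)],
                                 method="endpoints")
        assert tr.slope == pytest.approx(-0.02)
        assert tr.level == 0.06  # raw final observation

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 1.0), st.floats(-0.05, 0.05))
    def test_collinear_residuals_are_zero(self, level, slope):
        """Any line through the window is reproduced exactly (residual 0)."""
        ys = {t: min(1.0, max(0.0, level + slope * (t - 2000))) for t in
              (1998, 1999, 2000)}
        raw = [level + slope * (t - 2000) for t in (1998, 1999, 2000)]
        if any(not (0 <= v <= 1) for v in raw):
            return  # clamped inputs are no longer collinear
        tr = cs.fit_linear_trend(ys.items())
        for t in (1998, 1999, 2000):
            assert tr.predict(t) == pytest.approx(ys[t], abs=1e-12)


class TestProjection:
    def surface(self, level, slope):
        lv = np.full(TrendSurface.SHAPE, level)
        sl = np.full(TrendSurface.SHAPE, slope)
        return TrendSurface(2000, lv, sl, observed=lv.copy())

    def test_linear_extrapolation_value(self):
        t = self.surface(0.08, -0.01).project(2001, 2010)
        assert t.get_risk(2005, "male", 50, HistoryState.NO_HISTORY,
                          EventType.PCI) == pytest.approx(0.03)

    def test_floor_clamp(self):
        t = self.surface(0.08, -0.01).project(2001, 2010, floor=0.0)
        # raw 2010 value is 0.08 - 0.01*10 = -0.02, clamped to the floor
        assert t.get_risk(2010, "female", 70, HistoryState.CABG_HISTORY,
                          EventType.CABG) == 0.0

    def test_zero_slope_identity(self):
        t = self.surface(0.04, 0.0).project(2001, 2010)
        assert np.all(t.values == 0.04)

    def test_cap_clamp_keeps_values_in_bounds(self):
        surf = self.surface(0.02, 0.0)
        surf.slope[..., int(EventType.PCI)] = 0.2  # would hit 2.02 by 2010
        t = surf.project(2001, 2010, cap=0.5)
        assert np.all((t.values >= 0.0) & (t.values <= 0.5))
        assert t.get_risk(2010, "male", 50, HistoryState.NO_HISTORY,
                          EventType.PCI) == 0.5

    def test_sum_violation_raised_not_returned(self):
        with pytest.raises(cs.TableValidationError, match="sum exceeds"):
            self.surface(0.2, 0.05).project(2001, 2010)

    def test_invalid_floor_cap(self):
        with pytest.raises(cs.DomainError):
            self.surface(0.05, 0.0).project(2001, 2010, floor=0.5, cap=0.4)


class TestTrendSurfaceFromTable:
    def test_matches_scalar_fit_cell_by_cell(self):
        rng = np.random.default_rng(42)
        hist = cs.AnnualRiskTable(1998, 2000, rng.random((3, 2, 9, 4, 5)) * 0.05)
        surf = TrendSurface.from_table(hist)
        for sex, band, state, event in [
            ("male", "35-39", HistoryState.NO_HISTORY, EventType.PCI),
            ("female", "75-79", HistoryState.CABG_HISTORY, EventType.CHD_DEATH),
            ("male", "55-59", HistoryState.CHD_NO_CARP, EventType.CABG),
        ]:
            obs = [
                (y, hist.get_risk(y, sex, int(band.split("-")[0]), state, event))
                for y in (1998, 1999, 2000)
            ]
            scalar = cs.fit_linear_trend(obs)
            cell = surf.cell(sex, band, state, event)
            assert cell.slope == pytest.approx(scalar.slope, abs=1e-14)
            assert cell.level == pytest.approx(scalar.level, abs=1e-14)

    def test_logit_scale_recovers_logit_linear_risks_exactly(self):
        """The noise-free synthetic risks are exactly linear on the logit
        scale, so a logit-scale fit reproduces them and its long-horizon
        projection stays strictly inside (0, 1) without clamping."""
        cfg = cs.SyntheticConfig(noise_sd=0.0)
        hist = cs.generate_risk_history(cfg, 1998, 2000)
        surf = TrendSurface.from_table(hist, scale="logit")
        refit = surf.project(1998, 2000)
        assert np.allclose(refit.values, hist.values, atol=1e-12)
        proj = surf.project(2001, 2050)
        assert np.all((proj.values > 0.0) & (proj.values < 1.0))

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        hist = cs.AnnualRiskTable(1998, 2000, rng.random((3, 2, 9, 4, 5)) * 0.05)
        surf = TrendSurface.from_table(hist)
        path = tmp_path / "trends.csv"
        surf.write_csv(path)
        back = TrendSurface.read_csv(path)
        assert np.allclose(back.level, surf.level)
        assert np.allclose(back.slope, surf.slope)
        assert back.reference_year == surf.reference_year

    def test_missing_window_cells_rejected(self):
        hist = cs.AnnualRiskTable(1998, 2000)  # all NaN
        with pytest.raises(cs.TableValidationError):
            TrendSurface.from_table(hist)
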