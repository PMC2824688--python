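"""Scenario specifications and their application to projections."""

import numpy as np
import pytest

import carpsim as cs
from carpsim.states import EventType, HistoryState
from carpsim.trends import TrendSurface


def surface(level=0.05, slope=-0.002):
    lv = np.full(TrendSurface.SHAPE, level)
    sl = np.full(TrendSurface.SHAPE, slope)
    obs = lv + 0.001  # distinct raw observation for the level_off_at switch
    return TrendSurface(2000, lv, sl, observed=obs)


class TestBuiltinScenarios:
    def test_five_scenarios(self):
        specs = {s.name: s for s in cs.builtin_scenarios()}
        assert set(specs) == {"base", "incidence1", "incidence2", "incidence3",
                              "incidence4"}

    def test_base_is_empty(self):
        assert cs.builtin_scenario("base").modifications == ()

    def test_incidence1_levels_off_admission(self):
        (mod,) = cs.builtin_scenario("incidence1").modifications
        assert mod.kind == "level_off"
        assert mod.events == (EventType.CHD_ADMISSION_NO_CARP,)
        assert mod.states == (HistoryState.NO_HISTORY,)

    @pytest.mark.parametrize("name,factor", [("incidence2", 1.10),
                                             ("incidence3", 1.20)])
    def test_incidence_scalings(self, name, factor):
        (mod,) = cs.builtin_scenario(name).modifications
        assert mod.kind == "scale" and mod.factor == pytest.approx(factor)
        assert mod.events == (EventType.CHD_ADMISSION_NO_CARP,)

    def test_incidence4_combination(self):
        mods = cs.builtin_scenario("incidence4").modifications
        assert len(mods) == 4
        by_event = {m.events[0]: m for m in mods}
        assert by_event[EventType.CHD_ADMISSION_NO_CARP].factor == pytest.approx(1.20)
        assert by_event[EventType.PCI].factor == pytest.approx(1.05)
        assert by_event[EventType.CABG].kind == "level_off"
        assert by_event[EventType.CHD_DEATH].kind == "level_off"
        assert all(m.states == (HistoryState.NO_HISTORY,) for m in mods)


class TestModificationValidation:
    def test_scale_needs_positive_factor(self):
        with pytest.raises(cs.ConfigError):
            cs.Modification(events=(EventType.PCI,), kind="scale", factor=0.0)

    def test_unknown_kind(self):
        with pytest.raises(cs.ConfigError):
            cs.Modification(events=(EventType.PCI,), kind="wobble")

    def test_no_events(self):
        with pytest.raises(cs.ConfigError):
            cs.Modification(events=(), kind="level_off")


class TestApplyScenario:
    def test_empty_spec_is_identity(self):
        surf = surface()
        proj = surf.project(2001, 2010)
        out = cs.apply_scenario(proj, surf, cs.ScenarioSpec("base"))
        assert out == proj

    def test_scale_multiplies_projection(self):
        surf = surface(level=0.05, slope=0.0)
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=(EventType.CHD_ADMISSION_NO_CARP,), kind="scale", factor=1.2),))
        out = cs.apply_scenario(proj, surf, spec)
        v = out.get_risk(2005, "male", 50, HistoryState.NO_HISTORY,
                         EventType.CHD_ADMISSION_NO_CARP)
        assert v == pytest.approx(0.06)

    def test_level_off_holds_fitted_2000_value(self):
        surf = surface(level=0.08, slope=-0.01)
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("lvl", (cs.Modification(
            events=(EventType.CHD_ADMISSION_NO_CARP,), kind="level_off"),))
        out = cs.apply_scenario(proj, surf, spec)
        for year in range(2001, 2011):
            assert out.get_risk(year, "female", 60, HistoryState.NO_HISTORY,
                                EventType.CHD_ADMISSION_NO_CARP) == pytest.approx(0.08)

    def test_level_off_at_observed_switch(self):
        surf = surface(level=0.05, slope=-0.002)
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("lvl", (cs.Modification(
            events=(EventType.PCI,), kind="level_off"),))
        out = cs.apply_scenario(proj, surf, spec, level_off_at="observed")
        assert out.get_risk(2010, "male", 40, HistoryState.NO_HISTORY,
                            EventType.PCI) == pytest.approx(0.051)

    def test_untargeted_cells_bit_identical(self):
        surf = surface()
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=(EventType.PCI,), kind="scale", factor=1.3),))
        out = cs.apply_scenario(proj, surf, spec)
        mask = spec.modifications[0].mask()
        assert np.array_equal(out.values[:, ~mask], proj.values[:, ~mask])

    def test_scale_up_never_decreases_target(self):
        surf = surface()
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=(EventType.PCI,), kind="scale", factor=1.5,
            states=tuple(HistoryState)),))
        out = cs.apply_scenario(proj, surf, spec)
        assert np.all(out.values >= proj.values)

    def test_level_off_of_declining_risk_never_decreases(self):
        surf = surface(level=0.05, slope=-0.004)
        proj = surf.project(2001, 2010)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=(EventType.CHD_ADMISSION_NO_CARP,), kind="level_off",
            states=tuple(HistoryState)),))
        out = cs.apply_scenario(proj, surf, spec)
        assert np.all(out.values >= proj.values - 1e-15)

    def test_sum_violation_after_scaling_raises(self):
        surf = surface(level=0.199, slope=0.0)  # valid base sum 0.995
        proj = surf.project(2001, 2001)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=tuple(EventType), kind="scale", factor=1.2,
            states=tuple(HistoryState)),))
        with pytest.raises(cs.TableValidationError):
            cs.apply_scenario(proj, surf, spec)

    def test_sex_and_band_filters(self):
        surf = surface(level=0.05, slope=0.0)
        proj = surf.project(2001, 2002)
        spec = cs.ScenarioSpec("x", (cs.Modification(
            events=(EventType.PCI,), kind="scale", factor=2.0,
            sexes=("female",), age_bands=("45-49",)),))
        out = cs.apply_scenario(proj, surf, spec)
        assert out.get_risk(2001, "female", 47, HistoryState.NO_HISTORY,
                            EventType.PCI) == pytest.approx(0.10)
        assert out.get_risk(2001, "male", 47, HistoryState.NO_HISTORY,
                            EventType.PCI) == pytest.approx(0.05)
        assert out.get_risk(2001, "female", 52, HistoryState.NO_HISTORY,
                            EventType.PCI) == pytest.approx(0.05)


class TestScenarioJson:
    def test_round_trip(self):
        for spec in cs.builtin_scenarios():
            assert cs.ScenarioSpec.from_json(spec.to_json()) == spec

    def test_documented_shape(self):
        spec = cs.ScenarioSpec.from_json(
            '{"name": "custom", "modifications": '
            '[{"events": ["PCI"], "states": ["NO_HISTORY"], '
            '"kind": "scale", "factor": 1.2}]}'
        )
        assert spec.modifications[0].factor == pytest.approx(1.2)

    def test_bad_json_rejected(self):
        with pytest.raises(cs.ConfigError):
            cs.ScenarioSpec.from_json("{not json")
        with pytest.raises(cs.ConfigError):
            cs.ScenarioSpec.from_json('{"modifications": []}')
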