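"""Scenario orchestration and comparison tables.

Reproduces the study's headline summary: for each scenario, the total
projected numbers of CABGs and PCIs over the simulation horizon
(replicate-averaged sums of per-year counts) and their percent change
relative to the Base scenario, displayed to two decimal places.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BaselineCohort
from .engine import SimulationResult, run_replicates
from .errors import ConfigError, DomainError
from .expectation import ExpectedResult, expected_counts
from .scenarios import ScenarioSpec, apply_scenario, builtin_scenarios
from .states import EventType
from .trends import TrendSurface

__all__ = ["percent_change", "ScenarioComparison", "run_scenarios", "render_table"]

#: The events the comparison table reports (revascularization procedures).
CARP_EVENTS = (EventType.CABG, EventType.PCI)


def percent_change(base_total: float, scenario_total: float) -> float:
    """Percent change of a scenario total relative to the Base total.

    ``100 * (scenario_total - base_total) / base_total``; exact zero for
    identical totals.  Unrounded — display rounding is the renderer's job.
    """
    if base_total <= 0:
        raise DomainError(f"base total must be positive, got {base_total}")
    if scenario_total == base_total:
        return 0.0
    return 100.0 * (scenario_total - base_total) / base_total


@dataclasses.dataclass
class ScenarioComparison:
    """Totals and percent changes vs Base, plus per-year series.

    ``totals[name][event]`` is the horizon total for that scenario
    (replicate-averaged in simulation mode, exact in expected mode);
    ``series[name]`` maps each event to its per-year array.
    """

    scenario_names: list[str]
    base_name: str
    events: tuple[EventType, ...]
    totals: dict[str, dict[EventType, float]]
    series: dict[str, dict[EventType, np.ndarray]]
    years: list[int]
    mode: str  # "simulated" | "expected"
    results: dict[str, SimulationResult | ExpectedResult] = dataclasses.field(
        default_factory=dict, repr=False
    )

    def pct_change(self, name: str, event: EventType) -> float:
        return percent_change(self.totals[self.base_name][event],
                              self.totals[name][event])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.scenario_names:
            for ev in self.events:
                rows.append(
                    {
                        "scenario": name,
                        "event": ev.name,
                        "total": self.totals[name][ev],
                        "pct_change_vs_base": self.pct_change(name, ev),
                    }
                )
        return pd.DataFrame(rows)

    def series_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.scenario_names:
            for ev in self.events:
                for year, count in zip(self.years, self.series[name][ev]):
                    rows.append({"scenario": name, "event": ev.name,
                                 "year": year, "count": float(count)})
        return pd.DataFrame(rows)


def run_scenarios(
    cohort: BaselineCohort,
    trends: TrendSurface,
    specs: Sequence[ScenarioSpec] | None = None,
    start_year: int = 2001,
    end_year: int = 2010,
    n_replicates: int = 100,
    master_seed: int = 0,
    mode: str = "simulated",
    common_random_numbers: bool = True,
    level_off_at: str = "fitted",
    floor: float = 0.0,
    cap: float = 1.0,
    events: tuple[EventType, ...] = CARP_EVENTS,
) -> ScenarioComparison:
    """Project, modify and simulate every scenario; compare against Base.

    The Base scenario is always included (prepended when absent).  In
    simulation mode all scenarios share one master seed by default
    (common random numbers: scenario contrasts are then free of
    between-stream Monte Carlo noise); pass
    ``common_random_numbers=False`` for independent replicate streams.
    ``mode="expected"`` swaps the stochastic engine for the deterministic
    expectation twin.
    """
    specs = list(builtin_scenarios()) if specs is None else list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate scenario names: {names}")
    base = next((s for s in specs if s.is_base), None)
    if base is None:
        base = ScenarioSpec("base")
        if "base" in names:
            raise ConfigError("scenario named 'base' must have no modifications")
        specs.insert(0, base)
    if mode not in ("simulated", "expected"):
        raise ConfigError(f"unknown mode {mode!r}")

    projected = trends.project(start_year, end_year, floor=floor, cap=cap)
    totals: dict[str, dict[EventType, float]] = {}
    series: dict[str, dict[EventType, np.ndarray]] = {}
    results: dict[str, SimulationResult | ExpectedResult] = {}
    years = list(range(start_year, end_year + 1))

    for i, spec in enumerate(specs):
        table = apply_scenario(projected, trends, spec, level_off_at=level_off_at)
        if mode == "expected":
            res: SimulationResult | ExpectedResult = expected_counts(
                cohort, table, start_year, end_year, scenario_name=spec.name
            )
            per_year = res.counts
        else:
            seed = master_seed if common_random_numbers else master_seed + i
            res = run_replicates(
                cohort, table, start_year, end_year,
                n_replicates=n_replicates, master_seed=seed,
                scenario_name=spec.name,
            )
            per_year = res.averaged
        totals[spec.name] = {ev: float(per_year[:, int(ev)].sum()) for ev in events}
        series[spec.name] = {ev: per_year[:, int(ev)].copy() for ev in events}
        results[spec.name] = res

    return ScenarioComparison(
        scenario_names=[s.name for s in specs],
        base_name=base.name,
        events=tuple(events),
        totals=totals,
        series=series,
        years=years,
        mode=mode,
        results=results,
    )


def render_table(
    comparison: ScenarioComparison,
    round_totals: bool = False,
) -> tuple[pd.DataFrame, str]:
    """Render the comparison as (tidy DataFrame, human-readable text).

    Percent changes are computed from unrounded totals and displayed to
    two decimal places; ``round_totals`` additionally displays totals as
    integers.
    """
    df = comparison.to_frame()
    lines = []
    names = comparison.scenario_names
    header = ["Total event"] + names
    widths = [max(14, len(h) + 2) for h in header]
    widths[0] = max(widths[0], 22)

    def fmt_row(cells):
        return "".join(str(c).ljust(w) for c, w in zip(cells, widths))

    lines.append(fmt_row(header))
    for ev in comparison.events:
        row = [ev.name]
        for name in names:
            t = comparison.totals[name][ev]
            row.append(f"{t:.0f}" if round_totals else f"{t:.1f}")
        lines.append(fmt_row(row))
        pct_row = ["  % change vs base "]
        for name in names:
            if name == comparison.base_name:
                pct_row.append("---")
            else:
                pct_row.append(f"{comparison.pct_change(name, ev):.2f}")
        lines.append(fmt_row(pct_row))
    return df, "\n".join(lines)


def write_comparison(
    comparison: ScenarioComparison, out_dir: str | Path, round_totals: bool = False
) -> str:
    """Write comparison.csv and series.csv under *out_dir*; return text table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df, text = render_table(comparison, round_totals=round_totals)
    df.to_csv(out / "comparison.csv", index=False)
    comparison.series_frame().to_csv(out / "series.csv", index=False)
    return text
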