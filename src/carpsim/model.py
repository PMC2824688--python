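"""Model/Results front end for the CHD/CARP projection workflow.

:class:`CarpProjectionModel` is built from the two data inputs — a
baseline cohort and a historical annual-risk table — exactly the way a
statsmodels model is built from endog/exog.  ``fit()`` estimates the
per-cell linear risk trends over the fitting window (1998-2000 by
default) and returns a :class:`CarpTrendResults`, which carries the
estimates (levels, slopes, slope standard errors), exposes projection,
stochastic simulation, expectation and scenario comparison, and prints a
``summary()``.

Typical use::

    from carpsim import CarpProjectionModel, SyntheticConfig

    model = CarpProjectionModel.from_synthetic(SyntheticConfig(seed=7))
    res = model.fit()
    print(res.summary())
    comparison = res.compare(n_replicates=100, master_seed=7)
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .cohort import BaselineCohort
from .engine import SimulationResult, run_replicates
from .expectation import ExpectedResult, expected_counts
from .report import ScenarioComparison, run_scenarios
from .risks import AnnualRiskTable
from .scenarios import ScenarioSpec, apply_scenario
from .states import EventType
from .synthetic import SyntheticConfig, generate_cohort, generate_risk_history
from .trends import TrendSurface

__all__ = ["CarpProjectionModel", "CarpTrendResults"]


class CarpProjectionModel:
    """Markov microsimulation model of CARP demand for a closed cohort.

    Parameters
    ----------
    cohort
        Baseline population (sex, integer age 35-79, CHD/CARP history
        state per person).
    risk_history
        Historical :class:`AnnualRiskTable` covering at least the
        fitting window.
    fit_years
        Calendar years whose risks anchor the linear trends; the last is
        the reference year held fixed under level-off scenarios.
    """

    def __init__(
        self,
        cohort: BaselineCohort,
        risk_history: AnnualRiskTable,
        fit_years: Sequence[int] = (1998, 1999, 2000),
    ):
        self.cohort = cohort
        self.risk_history = risk_history
        self.fit_years = tuple(sorted(fit_years))
        for year in self.fit_years:
            risk_history.year_index(year)  # raises if not covered

    @classmethod
    def from_synthetic(
        cls,
        config: SyntheticConfig | None = None,
        history_years: tuple[int, int] = (1990, 2000),
        fit_years: Sequence[int] = (1998, 1999, 2000),
    ) -> "CarpProjectionModel":
        """Build the model from the synthetic-data generator."""
        config = config or SyntheticConfig()
        return cls(
            cohort=generate_cohort(config),
            risk_history=generate_risk_history(config, *history_years),
            fit_years=fit_years,
        )

    @classmethod
    def from_csv(
        cls,
        cohort_path,
        risks_path,
        fit_years: Sequence[int] = (1998, 1999, 2000),
        baseline_year: int = 2001,
    ) -> "CarpProjectionModel":
        return cls(
            cohort=BaselineCohort.read_csv(cohort_path, baseline_year=baseline_year),
            risk_history=AnnualRiskTable.read_csv(risks_path),
            fit_years=fit_years,
        )

    def fit(self, method: str = "ols", scale: str = "probability") -> "CarpTrendResults":
        """Fit the per-cell linear risk trends.

        ``method`` is ``"ols"`` or ``"endpoints"``; ``scale`` selects the
        fitting scale (``"probability"`` or ``"logit"``).
        """
        trends = TrendSurface.from_table(
            self.risk_history, fit_years=self.fit_years, method=method, scale=scale
        )
        return CarpTrendResults(self, trends, method=method)


class CarpTrendResults:
    """Fitted trends plus everything that hangs off them."""

    def __init__(self, model: CarpProjectionModel, trends: TrendSurface, method: str):
        self.model = model
        self.trends = trends
        self.method = method

    # -- estimates -----------------------------------------------------

    @property
    def params(self) -> pd.DataFrame:
        """Per-cell estimates: level, slope and (for OLS) slope SE."""
        df = self.trends.to_frame()
        if self.trends.slope_se is not None:
            df["slope_se"] = self.trends.slope_se.ravel()
        return df

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels style."""
        t = self.trends
        n_cells = t.level.size
        lines = [
            "            CHD/CARP trend-projection model",
            "=" * 60,
            f"Cohort size:           {len(self.model.cohort):>10d}",
            f"Baseline year:         {self.model.cohort.baseline_year:>10d}",
            f"Fitting window:        {self.model.fit_years[0]}-{self.model.fit_years[-1]}",
            f"Reference year:        {t.reference_year:>10d}",
            f"Fit method / scale:    {self.method} / {t.scale}",
            f"Risk cells fitted:     {n_cells:>10d}",
            "-" * 60,
            "Mean fitted level and slope by event "
            f"({'probability' if t.scale == 'probability' else 'logit'} scale):",
        ]
        for ev in EventType:
            lvl = float(t.level[..., int(ev)].mean())
            slp = float(t.slope[..., int(ev)].mean())
            lines.append(f"  {ev.name:<24s} level {lvl:>9.5f}   slope {slp:>+9.6f}/yr")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- projection and simulation --------------------------------------

    def project(
        self,
        start_year: int = 2001,
        end_year: int = 2010,
        floor: float = 0.0,
        cap: float = 1.0,
        scenario: ScenarioSpec | None = None,
        level_off_at: str = "fitted",
    ) -> AnnualRiskTable:
        """Trend-extrapolated risks, optionally under a scenario."""
        table = self.trends.project(start_year, end_year, floor=floor, cap=cap)
        if scenario is not None:
            table = apply_scenario(table, self.trends, scenario,
                                   level_off_at=level_off_at)
        return table

    def simulate(
        self,
        scenario: ScenarioSpec | None = None,
        start_year: int = 2001,
        end_year: int = 2010,
        n_replicates: int = 100,
        master_seed: int = 0,
        **project_kw,
    ) -> SimulationResult:
        """Stochastic replicate-averaged simulation under a scenario."""
        table = self.project(start_year, end_year, scenario=scenario, **project_kw)
        return run_replicates(
            self.model.cohort, table, start_year, end_year,
            n_replicates=n_replicates, master_seed=master_seed,
            scenario_name=scenario.name if scenario else "base",
        )

    def expected(
        self,
        scenario: ScenarioSpec | None = None,
        start_year: int = 2001,
        end_year: int = 2010,
        **project_kw,
    ) -> ExpectedResult:
        """Exact expected counts (the deterministic expectation twin)."""
        table = self.project(start_year, end_year, scenario=scenario, **project_kw)
        return expected_counts(
            self.model.cohort, table, start_year, end_year,
            scenario_name=scenario.name if scenario else "base",
        )

    def compare(
        self,
        scenarios: Sequence[ScenarioSpec] | None = None,
        start_year: int = 2001,
        end_year: int = 2010,
        n_replicates: int = 100,
        master_seed: int = 0,
        mode: str = "simulated",
        **kw,
    ) -> ScenarioComparison:
        """Run the scenario battery (built-ins by default) against Base."""
        return run_scenarios(
            self.model.cohort, self.trends, specs=scenarios,
            start_year=start_year, end_year=end_year,
            n_replicates=n_replicates, master_seed=master_seed, mode=mode, **kw,
        )

    # -- plotting convenience -------------------------------------------

    def plot_series(self, comparison: ScenarioComparison, ax=None):
        """Per-year CABG/PCI series per scenario (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in comparison.scenario_names:
            for ev in comparison.events:
                ax.plot(comparison.years, comparison.series[name][ev],
                        label=f"{name}:{ev.name}")
        ax.set_xlabel("year")
        ax.set_ylabel("projected count")
        ax.legend(fontsize="x-small")
        return ax
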