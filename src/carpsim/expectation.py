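"""Deterministic expectation twin of the stochastic engine.

Instead of sampling, this module propagates probability mass over
(sex, attained age, history state) strata year by year, enumerating for
each stratum the *exact* outcome tree of the engine's within-year
sub-cycle rule (first categorical draw, then up to two follow-on
CARP-only draws at updated-state risks).  Because the same rule is
enumerated rather than approximated, the engine's replicate averages
converge to these expected counts exactly, which is what makes this
module usable as the engine's test oracle and as a noise-free
"expected mode" for scenario comparisons.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
import pandas as pd

from .cohort import BaselineCohort
from .errors import IncompleteTableError
from .risks import AnnualRiskTable
from .states import (
    AGE_CAP,
    AGE_MAX,
    AGE_MIN,
    EventType,
    HistoryState,
    N_EVENTS,
    N_SEXES,
    N_STATES,
    SEXES,
)

__all__ = ["StateDistribution", "ExpectedResult", "expected_counts"]

_ADM = int(EventType.CHD_ADMISSION_NO_CARP)
_CABG = int(EventType.CABG)
_PCI = int(EventType.PCI)
_CHD_D = int(EventType.CHD_DEATH)
_NON_D = int(EventType.NON_CHD_DEATH)

_N_AGES = AGE_MAX - AGE_MIN + 1  # attained ages 35..79


@dataclasses.dataclass
class StateDistribution:
    """Probability mass over (sex, age, state) plus absorbing tallies.

    ``alive[s, a, st]`` is the expected number of cohort members of sex
    ``s`` at attained age ``AGE_MIN + a`` in state ``st``; ``died`` and
    ``aged_out`` accumulate absorbed mass.  Total mass is conserved and
    equals the baseline cohort size.
    """

    alive: np.ndarray  # (2, 45, 4) float
    died: float = 0.0
    aged_out: float = 0.0

    @classmethod
    def from_cohort(cls, cohort: BaselineCohort) -> "StateDistribution":
        alive = np.zeros((N_SEXES, _N_AGES, N_STATES))
        np.add.at(alive, (cohort.sex_idx, cohort.age - AGE_MIN, cohort.state), 1.0)
        return cls(alive=alive)

    @property
    def total(self) -> float:
        return float(self.alive.sum() + self.died + self.aged_out)


def _sub_cycle_tree(
    start_state: int, risks: tuple[float, ...], carp_risks_by_state: tuple
) -> list:
    """Enumerate the within-year outcome tree for one starting state.

    ``risks`` are the five first-draw event probabilities for the
    starting state; ``carp_risks_by_state[st]`` gives (CABG, PCI) risks
    used by follow-on draws once the state has moved to ``st``.  Returns
    a list of branches ``(probability, event_counts[5], end_state, died)``
    whose probabilities sum to 1.
    """
    branches: list[tuple[float, np.ndarray, int, bool]] = []

    def carp_pair(st: int) -> tuple[float, float]:
        return carp_risks_by_state[st]

    def follow_on(prob: float, counts: np.ndarray, st: int, carps: int,
                  draws_left: int) -> None:
        """Recursive CARP-only follow-on draws."""
        if carps >= 2 or draws_left == 0:
            branches.append((prob, counts, st, False))
            return
        pc, pp = carp_pair(st)
        p_none = 1.0 - pc - pp
        if p_none > 0:
            branches.append((prob * p_none, counts, st, False))
        if pc > 0:
            c = counts.copy()
            c[_CABG] += 1
            follow_on(prob * pc, c, int(HistoryState.CABG_HISTORY),
                      carps + 1, draws_left - 1)
        if pp > 0:
            c = counts.copy()
            c[_PCI] += 1
            follow_on(prob * pp, c, max(st, int(HistoryState.PCI_NO_CABG)),
                      carps + 1, draws_left - 1)

    p_none = 1.0 - sum(risks)
    zero = np.zeros(N_EVENTS)
    if p_none > 0:
        branches.append((p_none, zero, start_state, False))
    for e, p in enumerate(risks):
        if p <= 0:
            continue
        counts = zero.copy()
        counts[e] += 1
        if e in (_CHD_D, _NON_D):
            branches.append((p, counts, start_state, True))
        elif e == _ADM:
            s1 = max(start_state, int(HistoryState.CHD_NO_CARP))
            # an admission permits follow-on draws until two CARPs are done
            follow_on(p, counts, s1, carps=0, draws_left=2)
        elif e == _CABG:
            follow_on(p, counts, int(HistoryState.CABG_HISTORY),
                      carps=1, draws_left=1)
        elif e == _PCI:
            follow_on(p, counts, max(start_state, int(HistoryState.PCI_NO_CABG)),
                      carps=1, draws_left=1)
    return branches


@dataclasses.dataclass
class ExpectedResult:
    """Expected per-year event counts and the final mass distribution."""

    start_year: int
    end_year: int
    counts: np.ndarray  # (n_years, n_events) float
    final: StateDistribution
    scenario_name: str | None = None

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def total(self, event: EventType) -> float:
        return float(self.counts[:, int(event)].sum())

    def averaged_frame(self) -> pd.DataFrame:
        rows = []
        for yi, year in enumerate(self.years):
            for e in EventType:
                rows.append({"year": year, "event": e.name,
                             "mean_count": self.counts[yi, int(e)]})
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "scenario": self.scenario_name,
            "mode": "expected",
        }


def expected_counts(
    cohort: BaselineCohort,
    table: AnnualRiskTable,
    start_year: int,
    end_year: int,
    scenario_name: str | None = None,
) -> ExpectedResult:
    """Exact expected event counts under the engine's sub-cycle rule.

    Aggregates the cohort into (sex, age, state) mass, then for each
    person-year enumerates the full sub-cycle outcome tree, accumulating
    event-count expectations and propagating end-of-year state mass.
    Mass is conserved (alive + died + aged out = cohort size) at every
    year boundary.
    """
    dist = StateDistribution.from_cohort(cohort)
    n_years = end_year - start_year + 1
    counts = np.zeros((n_years, N_EVENTS))
    vals = table.values

    for yi_out, year in enumerate(range(start_year, end_year + 1)):
        yi = table.year_index(year)

        @lru_cache(maxsize=None)
        def tree(si: int, band: int, st: int):
            cell = vals[yi, si, band, :, :]  # (4, 5)
            if np.isnan(cell).any():
                e = int(np.argwhere(np.isnan(cell))[0][1])
                raise IncompleteTableError(
                    "incomplete risk table in expectation: missing cell "
                    f"(year={year}, sex={SEXES[si]}, band_index={band}, "
                    f"event={EventType(e).name})"
                )
            risks = tuple(float(p) for p in cell[st])
            carp = tuple((float(cell[s, _CABG]), float(cell[s, _PCI]))
                         for s in range(N_STATES))
            return _sub_cycle_tree(st, risks, carp)

        new_alive = np.zeros_like(dist.alive)
        for si, ai, st in zip(*np.nonzero(dist.alive)):
            m = dist.alive[si, ai, st]
            age = AGE_MIN + int(ai)
            band = (age - AGE_MIN) // 5
            for prob, ev_counts, end_state, died in tree(int(si), int(band), int(st)):
                pm = m * prob
                counts[yi_out] += pm * ev_counts
                if died:
                    dist.died += pm
                else:
                    new_age = age + 1
                    if new_age >= AGE_CAP:
                        dist.aged_out += pm
                    else:
                        new_alive[si, new_age - AGE_MIN, end_state] += pm
        dist = StateDistribution(new_alive, died=dist.died, aged_out=dist.aged_out)

    return ExpectedResult(
        start_year=start_year,
        end_year=end_year,
        counts=counts,
        final=dist,
        scenario_name=scenario_name,
    )
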