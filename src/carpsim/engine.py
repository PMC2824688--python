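"""Stochastic year-by-year microsimulation of the cohort.

Within a simulated year each active person is resolved by a short
sub-cycle:

1. one categorical draw over the five annual events plus "no event",
   using the person's current-state risks;
2. either death event terminates the person immediately (mortality risk
   acts once per year and is not re-drawn after a procedure);
3. a CHD admission without a procedure updates the state
   (no-history -> CHD-no-CARP) and permits one follow-on draw restricted
   to {CABG, PCI, none} at the *updated* state's risks;
4. a CABG or PCI updates the state immediately (CABG -> CABG history;
   PCI -> PCI-no-CABG unless CABG history already) and likewise permits
   one follow-on CARP-only draw;
5. at most two revascularizations per year, after which the year ends;
6. the survivor's age increments; reaching the age cap (80) removes the
   person from further simulation.

So a year can record at most three events (an admission followed by two
procedures), states only ever move up the dominance order, and risks are
re-looked-up at attained age each year.

Randomness: each replicate draws an independent substream from the
master seed via ``numpy.random.SeedSequence`` spawning.  Within a
replicate the cohort-level simulation consumes exactly three uniforms
per baseline person per year, in a fixed order, whether or not the
person is still active — so each person's draws are a deterministic
function of (master seed, replicate, year, person index).  Running two
scenarios under one master seed therefore uses common random numbers:
their event streams differ only where the modified risks flip a draw.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BaselineCohort, Person
from .errors import DomainError
from .risks import AnnualRiskTable
from .states import AGE_CAP, EventType, HistoryState, N_EVENTS, SEXES

__all__ = [
    "YearOutcome",
    "ReplicateOutcome",
    "SimulationResult",
    "simulate_person_year",
    "simulate_cohort",
    "run_replicates",
]

_ADM = int(EventType.CHD_ADMISSION_NO_CARP)
_CABG = int(EventType.CABG)
_PCI = int(EventType.PCI)
_CHD_D = int(EventType.CHD_DEATH)
_NON_D = int(EventType.NON_CHD_DEATH)


@dataclasses.dataclass
class YearOutcome:
    """What happened to one person in one simulated year."""

    person_id: str
    year: int
    events: list[EventType]
    end_state: HistoryState
    died: bool
    aged_out: bool


@dataclasses.dataclass
class ReplicateOutcome:
    """Per-year event counts and end-of-run status for one replicate."""

    start_year: int
    counts: np.ndarray  # (n_years, n_events) int64
    n_alive: int
    n_died: int
    n_aged_out: int


# ----------------------------------------------------------------------
# Scalar reference implementation (one person, one year)
# ----------------------------------------------------------------------

def _state_after_carp(state: int, event: int) -> int:
    if event == _CABG:
        return int(HistoryState.CABG_HISTORY)
    return max(state, int(HistoryState.PCI_NO_CABG))


def simulate_person_year(
    person: Person, year: int, table: AnnualRiskTable, rng: np.random.Generator
) -> YearOutcome:
    """Simulate one year for one person, mutating the person in place.

    This is the readable scalar form of the sub-cycle rule; the cohort
    simulation uses an equivalent vectorised implementation.  Draws are
    consumed lazily (one uniform per draw actually made).
    """
    if not person.alive or person.aged_out:
        raise DomainError(f"person {person.id} is no longer active")
    state = int(person.state)
    events: list[EventType] = []
    died = False

    def carp_risks(s: int) -> tuple[float, float]:
        pc = table.get_risk(year, person.sex, person.age, HistoryState(s), EventType.CABG)
        pp = table.get_risk(year, person.sex, person.age, HistoryState(s), EventType.PCI)
        return pc, pp

    # first draw: categorical over the five events + none
    risks = [
        table.get_risk(year, person.sex, person.age, HistoryState(state), EventType(e))
        for e in range(N_EVENTS)
    ]
    u = rng.random()
    cum = np.cumsum(risks)
    first = int(np.searchsorted(cum, u, side="right"))  # 5 = no event

    n_carps = 0
    if first in (_CHD_D, _NON_D):
        events.append(EventType(first))
        died = True
    elif first == _ADM:
        events.append(EventType.CHD_ADMISSION_NO_CARP)
        state = max(state, int(HistoryState.CHD_NO_CARP))
    elif first in (_CABG, _PCI):
        events.append(EventType(first))
        state = _state_after_carp(state, first)
        n_carps = 1

    # follow-on CARP-only draws at the updated state's risks
    if not died and first != 5:
        while n_carps < 2:
            pc, pp = carp_risks(state)
            u = rng.random()
            if u < pc:
                events.append(EventType.CABG)
                state = _state_after_carp(state, _CABG)
                n_carps += 1
            elif u < pc + pp:
                events.append(EventType.PCI)
                state = _state_after_carp(state, _PCI)
                n_carps += 1
            else:
                break
            if first in (_CABG, _PCI):
                # a first-draw CARP permits a single follow-on draw
                break

    person.state = HistoryState(state)
    aged_out = False
    if died:
        person.alive = False
    else:
        person.age += 1
        if person.age >= AGE_CAP:
            person.aged_out = True
            aged_out = True
    return YearOutcome(
        person_id=person.id,
        year=year,
        events=events,
        end_state=HistoryState(state),
        died=died,
        aged_out=aged_out,
    )


# ----------------------------------------------------------------------
# Vectorised cohort simulation
# ----------------------------------------------------------------------

def simulate_cohort(
    cohort: BaselineCohort,
    table: AnnualRiskTable,
    start_year: int,
    end_year: int,
    rng: np.random.Generator,
) -> ReplicateOutcome:
    """One stochastic replicate of the whole cohort.

    Each person is simulated independently year by year until death, the
    age cap (80), or the end of the horizon.  Consumes exactly
    ``3 * n_persons`` uniforms per year in person order.
    """
    n = len(cohort)
    n_years = end_year - start_year + 1
    vals = table.values  # (n_years_table, 2, 9, 4, 5)

    age = cohort.age.copy()
    state = cohort.state.copy()
    sex = cohort.sex_idx
    alive = np.ones(n, dtype=bool)
    aged_out = np.zeros(n, dtype=bool)
    counts = np.zeros((n_years, N_EVENTS), dtype=np.int64)

    for yi_out, year in enumerate(range(start_year, end_year + 1)):
        u = rng.random((n, 3))
        active = alive & ~aged_out
        if not active.any():
            continue
        idx = np.nonzero(active)[0]
        yi = table.year_index(year)
        band = (age[idx] - 35) // 5
        probs = vals[yi, sex[idx], band, state[idx], :]  # (m, 5)
        if np.isnan(probs).any():
            _raise_missing(table, year, sex, age, state, idx, probs)
        cum = np.cumsum(probs, axis=1)
        first = (u[idx, 0][:, None] >= cum).sum(axis=1)  # 0..5, 5 = none

        for e in range(N_EVENTS):
            counts[yi_out, e] += int((first == e).sum())

        died_now = (first == _CHD_D) | (first == _NON_D)
        alive[idx[died_now]] = False

        # state updates from the first draw
        adm = first == _ADM
        state[idx[adm]] = np.maximum(state[idx[adm]], int(HistoryState.CHD_NO_CARP))
        cabg1 = first == _CABG
        state[idx[cabg1]] = int(HistoryState.CABG_HISTORY)
        pci1 = first == _PCI
        state[idx[pci1]] = np.maximum(state[idx[pci1]], int(HistoryState.PCI_NO_CABG))

        # follow-on draw 1: anyone whose first draw was an admission or a CARP
        elig1 = idx[adm | cabg1 | pci1]
        out1 = np.full(len(idx), -1)
        if len(elig1):
            out1_e = _carp_draw(vals, yi, sex, age, state, elig1, u[elig1, 1])
            counts[yi_out, _CABG] += int((out1_e == _CABG).sum())
            counts[yi_out, _PCI] += int((out1_e == _PCI).sum())
            c = elig1[out1_e == _CABG]
            state[c] = int(HistoryState.CABG_HISTORY)
            p = elig1[out1_e == _PCI]
            state[p] = np.maximum(state[p], int(HistoryState.PCI_NO_CABG))
            out1[np.searchsorted(idx, elig1)] = out1_e

        # follow-on draw 2: admission whose first follow-on was a CARP
        if len(elig1):
            adm_idx = idx[adm]
            pos = np.searchsorted(idx, adm_idx)
            had_carp = np.isin(out1[pos], (_CABG, _PCI))
            elig2 = adm_idx[had_carp]
            if len(elig2):
                out2_e = _carp_draw(vals, yi, sex, age, state, elig2, u[elig2, 2])
                counts[yi_out, _CABG] += int((out2_e == _CABG).sum())
                counts[yi_out, _PCI] += int((out2_e == _PCI).sum())
                c = elig2[out2_e == _CABG]
                state[c] = int(HistoryState.CABG_HISTORY)
                p = elig2[out2_e == _PCI]
                state[p] = np.maximum(state[p], int(HistoryState.PCI_NO_CABG))

        # survivors age by one year; the age cap removes them
        survivors = idx[~died_now]
        age[survivors] += 1
        aged_out[survivors[age[survivors] >= AGE_CAP]] = True

    n_died = int((~alive).sum())
    n_aged = int((alive & aged_out).sum())
    return ReplicateOutcome(
        start_year=start_year,
        counts=counts,
        n_alive=n - n_died - n_aged,
        n_died=n_died,
        n_aged_out=n_aged,
    )


def _carp_draw(vals, yi, sex, age, state, persons, u):
    """Follow-on draw over {CABG, PCI, none} at current-state risks."""
    band = (age[persons] - 35) // 5
    pc = vals[yi, sex[persons], band, state[persons], _CABG]
    pp = vals[yi, sex[persons], band, state[persons], _PCI]
    out = np.full(len(persons), -1)
    out[u < pc + pp] = _PCI
    out[u < pc] = _CABG
    return out


def _raise_missing(table, year, sex, age, state, idx, probs):
    from .errors import IncompleteTableError

    i, e = np.argwhere(np.isnan(probs))[0]
    pid = idx[i]
    raise IncompleteTableError(
        "incomplete risk table during simulation: missing cell "
        f"(year={year}, sex={SEXES[sex[pid]]}, age={age[pid]}, "
        f"state={HistoryState(int(state[pid])).name}, event={EventType(int(e)).name})"
    )


# ----------------------------------------------------------------------
# Replicate averaging
# ----------------------------------------------------------------------

@dataclasses.dataclass
class SimulationResult:
    """Replicate-level and replicate-averaged event counts.

    ``counts[r, y, e]`` is the number of occurrences of event ``e`` in
    year ``start_year + y`` of replicate ``r``; ``averaged`` is the mean
    over replicates.  Bit-exactly reproducible from (cohort, table,
    master_seed, n_replicates).
    """

    start_year: int
    end_year: int
    counts: np.ndarray          # (n_replicates, n_years, n_events) int64
    end_status: np.ndarray      # (n_replicates, 3): alive, died, aged_out
    n_replicates: int
    master_seed: int
    scenario_name: str | None = None

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def averaged(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def total(self, event: EventType) -> float:
        """Replicate-averaged total count of *event* over the horizon."""
        return float(self.averaged[:, int(event)].sum())

    def standard_error(self) -> np.ndarray:
        """Monte Carlo SE of ``averaged``, from replicate variance."""
        return self.counts.std(axis=0, ddof=1) / np.sqrt(self.n_replicates)

    def averaged_frame(self) -> pd.DataFrame:
        rows = []
        avg = self.averaged
        for yi, year in enumerate(self.years):
            for e in EventType:
                rows.append({"year": year, "event": e.name,
                             "mean_count": avg[yi, int(e)]})
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        r, y, e = np.indices(self.counts.shape).reshape(3, -1)
        return pd.DataFrame(
            {
                "replicate": r,
                "year": self.start_year + y,
                "event": [EventType(k).name for k in e],
                "count": self.counts[r, y, e],
            }
        )

    def metadata(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "scenario": self.scenario_name,
            "mode": "simulated",
        }

    def write_csv(self, out_dir: str | Path, prefix: str = "") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(out / f"{prefix}replicate_counts.csv", index=False)
        self.averaged_frame().to_csv(out / f"{prefix}averaged_counts.csv", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (
            self.start_year == other.start_year
            and self.end_year == other.end_year
            and self.n_replicates == other.n_replicates
            and self.master_seed == other.master_seed
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.end_status, other.end_status)
        )


def run_replicates(
    cohort: BaselineCohort,
    table: AnnualRiskTable,
    start_year: int,
    end_year: int,
    n_replicates: int = 100,
    master_seed: int = 0,
    scenario_name: str | None = None,
) -> SimulationResult:
    """Run *n_replicates* independent cohort simulations and average them.

    Replicate ``r`` uses the ``r``-th child of
    ``SeedSequence(master_seed)``, so results are bit-identical for
    identical inputs and seed, regardless of how replicates are batched.
    """
    if n_replicates < 1:
        raise DomainError(f"n_replicates must be >= 1, got {n_replicates}")
    n_years = end_year - start_year + 1
    counts = np.zeros((n_replicates, n_years, N_EVENTS), dtype=np.int64)
    status = np.zeros((n_replicates, 3), dtype=np.int64)
    children = np.random.SeedSequence(master_seed).spawn(n_replicates)
    for r, child in enumerate(children):
        rep = simulate_cohort(cohort, table, start_year, end_year,
                              np.random.default_rng(child))
        counts[r] = rep.counts
        status[r] = (rep.n_alive, rep.n_died, rep.n_aged_out)
    return SimulationResult(
        start_year=start_year,
        end_year=end_year,
        counts=counts,
        end_status=status,
        n_replicates=n_replicates,
        master_seed=master_seed,
        scenario_name=scenario_name,
    )
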