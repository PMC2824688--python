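"""Shared fixtures and the independent brute-force expectation oracle.

The brute-force oracle deliberately avoids the package's recursive tree
enumeration: it flat-enumerates all 54 potential draw triples
(first draw x two potential follow-on draws) of a person-year, walks the
documented within-year rule forward to decide which draws actually
happen, and chains person-years recursively across the horizon.  It is
O(54^years) per person and only usable on toy problems, which is the
point: it is an independent executable statement of the rule.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import carpsim as cs
from carpsim.states import AGE_CAP, EventType, HistoryState

ADM = EventType.CHD_ADMISSION_NO_CARP
CABG = EventType.CABG
PCI = EventType.PCI
CHD_D = EventType.CHD_DEATH
NON_D = EventType.NON_CHD_DEATH

FIRST_DRAW_OUTCOMES = [ADM, CABG, PCI, CHD_D, NON_D, "none"]
FOLLOW_OUTCOMES = [CABG, PCI, "none"]


def single_year_paths(table, year, sex, age, state):
    """All (probability, events, end_state, died) paths of one person-year.

    Flat enumeration over every potential draw triple; draws that the
    rule never reaches contribute no probability factor.
    """

    def risk(st, ev):
        return table.get_risk(year, sex, age, st, ev)

    paths = {}
    for d1, d2, d3 in itertools.product(FIRST_DRAW_OUTCOMES, FOLLOW_OUTCOMES,
                                        FOLLOW_OUTCOMES):
        st = state
        prob = 1.0
        events = []
        died = False
        # first draw: categorical over the five events + none
        if d1 == "none":
            prob *= 1.0 - sum(risk(st, e) for e in EventType)
        else:
            prob *= risk(st, d1)
        if prob == 0.0:
            continue
        used_follow = 0
        carps = 0
        if d1 in (CHD_D, NON_D):
            died = True
            events.append(d1)
        elif d1 == ADM:
            events.append(d1)
            st = max(st, HistoryState.CHD_NO_CARP)
        elif d1 in (CABG, PCI):
            events.append(d1)
            st = (HistoryState.CABG_HISTORY if d1 == CABG
                  else max(st, HistoryState.PCI_NO_CABG))
            carps = 1
        # follow-on draw 1 happens iff the first draw was an admission or CARP
        if not died and d1 not in ("none",) and carps < 2:
            pc, pp = risk(st, CABG), risk(st, PCI)
            prob *= {CABG: pc, PCI: pp, "none": 1.0 - pc - pp}[d2]
            used_follow = 1
            if prob == 0.0:
                continue
            if d2 != "none":
                events.append(d2)
                st = (HistoryState.CABG_HISTORY if d2 == CABG
                      else max(st, HistoryState.PCI_NO_CABG))
                carps += 1
            # follow-on draw 2 happens only after an admission whose first
            # follow-on was a CARP (a first-draw CARP permits one draw only)
            if d1 == ADM and d2 != "none" and carps < 2:
                pc, pp = risk(st, CABG), risk(st, PCI)
                prob *= {CABG: pc, PCI: pp, "none": 1.0 - pc - pp}[d3]
                used_follow = 2
                if prob == 0.0:
                    continue
                if d3 != "none":
                    events.append(d3)
                    st = (HistoryState.CABG_HISTORY if d3 == CABG
                          else max(st, HistoryState.PCI_NO_CABG))
                    carps += 1
        # collapse unreached draws so each realised path appears once
        key = (tuple(events), int(st), died, used_follow)
        reached = (d2 if used_follow >= 1 else None, d3 if used_follow == 2 else None)
        paths.setdefault((key, reached), prob)
    merged = {}
    for ((events, st, died, _), _reached), prob in paths.items():
        k = (events, st, died)
        merged[k] = merged.get(k, 0.0) + prob
    return [(p, list(ev), HistoryState(st), died) for (ev, st, died), p in merged.items()]


def brute_force_expected(cohort, table, start_year, end_year):
    """Exhaustive multi-year path enumeration of expected event counts."""
    n_years = end_year - start_year + 1
    counts = np.zeros((n_years, len(EventType)))

    def walk(sex, age, state, year_idx, mass):
        if year_idx == n_years or age >= AGE_CAP:
            return
        year = start_year + year_idx
        for prob, events, end_state, died in single_year_paths(
            table, year, sex, age, state
        ):
            pm = mass * prob
            if pm == 0.0:
                continue
            for ev in events:
                counts[year_idx, int(ev)] += pm
            if not died:
                walk(sex, age + 1, end_state, year_idx + 1, pm)

    for person in cohort.persons():
        walk(person.sex, person.age, person.state, 0, 1.0)
    return counts


# ----------------------------------------------------------------------
# Table-building helpers
# ----------------------------------------------------------------------

def uniform_table(start_year, end_year, risks_by_event=None, risks_by_state=None):
    """Complete table with identical risks in every stratum.

    ``risks_by_event`` is a 5-vector applied everywhere;
    ``risks_by_state`` maps HistoryState -> 5-vector and overrides it.
    """
    table = cs.AnnualRiskTable.full(start_year, end_year, 0.0)
    if risks_by_event is not None:
        table.values[...] = np.asarray(risks_by_event, dtype=float)
    if risks_by_state:
        for st, vec in risks_by_state.items():
            table.values[:, :, :, int(st), :] = np.asarray(vec, dtype=float)
    return table


@pytest.fixture(scope="session")
def synthetic_config():
    return cs.SyntheticConfig(seed=20250920)


@pytest.fixture(scope="session")
def fitted_results(synthetic_config):
    """Fitted trends on the default 10,000-person synthetic inputs."""
    model = cs.CarpProjectionModel.from_synthetic(synthetic_config)
    return model.fit()


@pytest.fixture(scope="session")
def small_fitted_results():
    """A 500-person model for cheap end-to-end checks."""
    cfg = cs.SyntheticConfig(n_persons=500, seed=11)
    return cs.CarpProjectionModel.from_synthetic(cfg).fit()
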