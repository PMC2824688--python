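"""Disease-history states, annual event types and stratification axes.

The model classifies every person at every point in time into one of four
mutually exclusive CHD/CARP history states, ordered by dominance: a CABG
ever recorded outranks any number of PCIs, which outrank a bare CHD
admission, which outranks no history at all.  Five annual events are
recognised; the two death events are absorbing.
"""

from __future__ import annotations

import enum

from .errors import DomainError

__all__ = [
    "HistoryState",
    "EventType",
    "SEXES",
    "AGE_BANDS",
    "AGE_MIN",
    "AGE_MAX",
    "AGE_CAP",
    "band_index_of_age",
    "band_label_of_age",
    "sex_index",
]


class HistoryState(enum.IntEnum):
    """CHD/CARP history state; integer value encodes the dominance order.

    A person's state can only move up this order (``NO_HISTORY`` ->
    ``CHD_NO_CARP`` -> ``PCI_NO_CABG`` -> ``CABG_HISTORY``), never down.
    """

    NO_HISTORY = 0
    CHD_NO_CARP = 1
    PCI_NO_CABG = 2
    CABG_HISTORY = 3


class EventType(enum.IntEnum):
    """Annual events a cohort member may experience.

    ``CHD_DEATH`` and ``NON_CHD_DEATH`` are absorbing: they terminate the
    person's simulation.  ``CHD_ADMISSION_NO_CARP`` is a CHD hospital
    admission in which no revascularization is performed; ``CABG`` and
    ``PCI`` are admissions with the respective procedure.
    """

    CHD_ADMISSION_NO_CARP = 0
    CABG = 1
    PCI = 2
    CHD_DEATH = 3
    NON_CHD_DEATH = 4


#: CARP = coronary artery revascularization procedure.
CARP_EVENTS = (EventType.CABG, EventType.PCI)
DEATH_EVENTS = (EventType.CHD_DEATH, EventType.NON_CHD_DEATH)

SEXES = ("male", "female")

AGE_MIN = 35
AGE_MAX = 79
#: Simulation removes a person once attained age reaches this cutoff.
AGE_CAP = 80

AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(AGE_MIN, AGE_MAX, 5))
N_BANDS = len(AGE_BANDS)  # 9 five-year bands, 35-39 .. 75-79
N_STATES = len(HistoryState)
N_EVENTS = len(EventType)
N_SEXES = len(SEXES)

#: Midpoint age of each 5-year band, used by the synthetic risk generator.
AGE_BAND_MIDPOINTS = tuple(lo + 2.0 for lo in range(AGE_MIN, AGE_MAX, 5))


def band_index_of_age(age: int) -> int:
    """Map a single-year attained age to the index of its 5-year band."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise DomainError(
            f"age {age} outside the modelled range {AGE_MIN}-{AGE_MAX}"
        )
    return (int(age) - AGE_MIN) // 5


def band_label_of_age(age: int) -> str:
    """Return the '35-39'-style label of the band containing *age*."""
    return AGE_BANDS[band_index_of_age(age)]


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise DomainError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def parse_state(code: str) -> HistoryState:
    try:
        return HistoryState[code]
    except KeyError:
        raise DomainError(
            f"unknown history state code {code!r}; expected one of "
            f"{[s.name for s in HistoryState]}"
        ) from None


def parse_event(code: str) -> EventType:
    try:
        return EventType[code]
    except KeyError:
        raise DomainError(
            f"unknown event code {code!r}; expected one of "
            f"{[e.name for e in EventType]}"
        ) from None
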