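"""Annual event-risk tables.

An :class:`AnnualRiskTable` stores, for each calendar year it covers, the
probability of each of the five annual events for every stratum
(sex x 5-year age band x history state).  Internally the table is a dense
float array indexed ``[year, sex, band, state, event]``; cells that were
never supplied are NaN, which lets a sparse CSV round-trip exactly and
makes missing-cell lookups loud.

The five event probabilities of a (year, stratum) cell are competing
risks: their sum must not exceed 1, and the residual mass ``1 - sum`` is
the probability of "no event this year".  Tables whose sums exceed 1 are
rejected rather than renormalized — silent renormalization would hide
input errors.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, IncompleteTableError, ParseError
from .states import (
    AGE_BANDS,
    EventType,
    HistoryState,
    N_BANDS,
    N_EVENTS,
    N_SEXES,
    N_STATES,
    SEXES,
    band_index_of_age,
    parse_event,
    parse_state,
    sex_index,
)

__all__ = [
    "Stratum",
    "AnnualRiskTable",
    "get_risk",
    "validate_table",
    "read_risk_csv",
    "write_risk_csv",
]

RISK_CSV_COLUMNS = ["year", "sex", "age_band", "state", "event", "probability"]

#: Tolerance on the competing-risk sum test.  Sums are compared against
#: 1 + SUM_TOL so that float rounding of five probabilities that add to
#: exactly one is not flagged.
SUM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class Stratum:
    """One risk-table stratum: sex, 5-year age band and history state."""

    sex: str
    age_band: str
    state: HistoryState

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise DomainError(
                f"unknown age band {self.age_band!r}; expected one of {AGE_BANDS}"
            )


class AnnualRiskTable:
    """Event probabilities per (year, sex, age band, state, event) cell.

    Parameters
    ----------
    start_year, end_year
        Inclusive calendar-year range the table declares to cover.
    values
        Optional array of shape ``(n_years, 2, 9, 4, 5)``; defaults to
        all-NaN (an empty table to be filled via :meth:`set_risk` or
        :meth:`from_entries`).
    """

    def __init__(self, start_year: int, end_year: int, values: np.ndarray | None = None):
        if end_year < start_year:
            raise DomainError(f"end_year {end_year} before start_year {start_year}")
        self.start_year = int(start_year)
        self.end_year = int(end_year)
        shape = (self.n_years, N_SEXES, N_BANDS, N_STATES, N_EVENTS)
        if values is None:
            values = np.full(shape, np.nan)
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != shape:
                raise DomainError(f"values shape {values.shape} != expected {shape}")
        self.values = values

    # -- basic protocol ------------------------------------------------

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def year_index(self, year: int) -> int:
        if not (self.start_year <= year <= self.end_year):
            raise IncompleteTableError(
                f"incomplete risk table: year {year} outside covered range "
                f"{self.start_year}-{self.end_year}"
            )
        return year - self.start_year

    def copy(self) -> "AnnualRiskTable":
        return AnnualRiskTable(self.start_year, self.end_year, self.values.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnualRiskTable):
            return NotImplemented
        return (
            self.start_year == other.start_year
            and self.end_year == other.end_year
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        n_set = int(np.isfinite(self.values).sum())
        return (
            f"AnnualRiskTable({self.start_year}-{self.end_year}, "
            f"{n_set}/{self.values.size} cells set)"
        )

    # -- cell access ---------------------------------------------------

    def set_risk(
        self,
        year: int,
        sex: str,
        age_band: str,
        state: HistoryState,
        event: EventType,
        probability: float,
    ) -> None:
        yi = self.year_index(year)
        bi = AGE_BANDS.index(age_band)
        self.values[yi, sex_index(sex), bi, int(state), int(event)] = probability

    def get_risk(
        self, year: int, sex: str, age: int, state: HistoryState, event: EventType
    ) -> float:
        """Look up the probability for the 5-year band containing *age*.

        Pure lookup: no interpolation, referentially transparent.  Raises
        :class:`IncompleteTableError` naming the cell when the cell was
        never provided, :class:`DomainError` when *age* lies outside the
        modelled 35-79 range.
        """
        yi = self.year_index(year)
        bi = band_index_of_age(age)
        v = self.values[yi, sex_index(sex), bi, int(state), int(event)]
        if np.isnan(v):
            raise IncompleteTableError(
                "incomplete risk table: missing cell "
                f"(year={year}, sex={sex}, age_band={AGE_BANDS[bi]}, "
                f"state={HistoryState(state).name}, event={EventType(event).name})"
            )
        return float(v)

    # -- validation ----------------------------------------------------

    def validate(self) -> list[str]:
        """Return every invariant violation (empty list when valid).

        Checks, over the declared year range: each probability in [0, 1];
        per-(year, stratum) competing-risk sums at most 1; no missing cell.
        Violations are returned, not raised.
        """
        violations: list[str] = []
        v = self.values
        for yi, si, bi, sti, ei in zip(*np.nonzero(np.isnan(v))):
            violations.append(
                "missing cell "
                f"(year={self.start_year + yi}, sex={SEXES[si]}, "
                f"age_band={AGE_BANDS[bi]}, state={HistoryState(sti).name}, "
                f"event={EventType(ei).name})"
            )
        bad = np.isfinite(v) & ((v < 0.0) | (v > 1.0))
        for yi, si, bi, sti, ei in zip(*np.nonzero(bad)):
            violations.append(
                f"probability out of range [0,1]: {v[yi, si, bi, sti, ei]!r} at "
                f"(year={self.start_year + yi}, sex={SEXES[si]}, "
                f"age_band={AGE_BANDS[bi]}, state={HistoryState(sti).name}, "
                f"event={EventType(ei).name})"
            )
        sums = np.nansum(v, axis=-1)
        over = sums > 1.0 + SUM_TOL
        for yi, si, bi, sti in zip(*np.nonzero(over)):
            violations.append(
                f"competing-risk sum exceeds 1: {sums[yi, si, bi, sti]:.6g} at "
                f"(year={self.start_year + yi}, sex={SEXES[si]}, "
                f"age_band={AGE_BANDS[bi]}, state={HistoryState(sti).name})"
            )
        return violations

    # -- construction / conversion --------------------------------------

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[tuple[int, str, str, HistoryState, EventType], float]
        | Iterable[tuple[int, str, str, HistoryState, EventType, float]],
        start_year: int | None = None,
        end_year: int | None = None,
    ) -> "AnnualRiskTable":
        """Build a (possibly sparse) table from explicit cell entries."""
        if isinstance(entries, Mapping):
            rows = [(*k, p) for k, p in entries.items()]
        else:
            rows = [tuple(r) for r in entries]
        if not rows:
            raise DomainError("cannot build a risk table from zero entries")
        years = [r[0] for r in rows]
        start_year = min(years) if start_year is None else start_year
        end_year = max(years) if end_year is None else end_year
        table = cls(start_year, end_year)
        for year, sex, band, state, event, p in rows:
            table.set_risk(year, sex, band, state, event, p)
        return table

    @classmethod
    def full(
        cls, start_year: int, end_year: int, probability: float | np.ndarray
    ) -> "AnnualRiskTable":
        """A complete table with every cell set to *probability*.

        *probability* may be a scalar or anything broadcastable to the
        per-year cell block ``(2, 9, 4, 5)`` (e.g. a 5-vector of per-event
        risks shared by all strata and years).
        """
        t = cls(start_year, end_year)
        t.values[...] = probability
        return t

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per non-missing cell."""
        yi, si, bi, sti, ei = np.nonzero(np.isfinite(self.values))
        return pd.DataFrame(
            {
                "year": self.start_year + yi,
                "sex": np.asarray(SEXES)[si],
                "age_band": np.asarray(AGE_BANDS)[bi],
                "state": [HistoryState(k).name for k in sti],
                "event": [EventType(k).name for k in ei],
                "probability": self.values[yi, si, bi, sti, ei],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnualRiskTable":
        missing = set(RISK_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"risk table missing columns: {sorted(missing)}")
        if df.empty:
            raise ParseError("risk table has no rows")
        table = cls(int(df["year"].min()), int(df["year"].max()))
        seen: set[tuple] = set()
        for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
            try:
                year = int(row.year)
                state = parse_state(str(row.state))
                event = parse_event(str(row.event))
                p = float(row.probability)
                key = (year, str(row.sex), str(row.age_band), state, event)
                if key in seen:
                    raise ParseError(f"duplicate cell {key}")
                seen.add(key)
                table.set_risk(year, str(row.sex), state=state, event=event,
                               age_band=str(row.age_band), probability=p)
            except (ParseError, DomainError, ValueError) as exc:
                raise ParseError(f"risk CSV row {i}: {exc}") from exc
        return table

    def write_csv(self, path: str | Path) -> None:
        # %.17g guarantees float64 round-trip identity through the CSV
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "AnnualRiskTable":
        try:
            # round_trip parsing keeps read(write(t)) == t bit-exact
            df = pd.read_csv(path, float_precision="round_trip")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot parse risk CSV {path}: {exc}") from exc
        return cls.from_frame(df)


# Module-level functional aliases ---------------------------------------


def get_risk(
    table: AnnualRiskTable,
    year: int,
    sex: str,
    age: int,
    state: HistoryState,
    event: EventType,
) -> float:
    """Functional form of :meth:`AnnualRiskTable.get_risk`."""
    return table.get_risk(year, sex, age, state, event)


def validate_table(table: AnnualRiskTable) -> list[str]:
    """Functional form of :meth:`AnnualRiskTable.validate`."""
    return table.validate()


def read_risk_csv(path: str | Path) -> AnnualRiskTable:
    return AnnualRiskTable.read_csv(path)


def write_risk_csv(table: AnnualRiskTable, path: str | Path) -> None:
    table.write_csv(path)
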