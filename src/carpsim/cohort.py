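"""Baseline cohorts: the persons the simulation follows.

A :class:`BaselineCohort` is a column-oriented store (ids, sex, age,
state as arrays) for speed; :class:`Person` is the record-oriented view
used by the single-person simulation operation and by tests.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError
from .states import AGE_MAX, AGE_MIN, HistoryState, SEXES, parse_state, sex_index

__all__ = ["Person", "BaselineCohort", "read_cohort_csv", "write_cohort_csv"]

COHORT_CSV_COLUMNS = ["id", "sex", "age", "state"]


@dataclasses.dataclass
class Person:
    """One cohort member.

    Age is integer attained age; at baseline it must lie in 35-79.  The
    simulation removes a person once attained age reaches 80 (``aged_out``)
    or on death (``alive`` cleared).
    """

    id: str
    sex: str
    age: int
    state: HistoryState
    alive: bool = True
    aged_out: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"person {self.id}: unknown sex {self.sex!r}")
        self.state = HistoryState(self.state)


class BaselineCohort:
    """Persons with sex, age and CHD/CARP history state at baseline.

    Invariants: unique ids, all persons alive, baseline ages within 35-79.
    """

    def __init__(
        self,
        ids: Sequence[str],
        sex_idx: np.ndarray,
        age: np.ndarray,
        state: np.ndarray,
        baseline_year: int = 2001,
    ):
        self.ids = np.asarray(ids, dtype=object)
        self.sex_idx = np.asarray(sex_idx, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.int64)
        self.state = np.asarray(state, dtype=np.int64)
        self.baseline_year = int(baseline_year)
        n = len(self.ids)
        if not (len(self.sex_idx) == len(self.age) == len(self.state) == n):
            raise DomainError("cohort column lengths differ")
        if n == 0:
            raise DomainError("cohort must contain at least one person")
        if len(set(self.ids.tolist())) != n:
            raise DomainError("duplicate person ids in cohort")
        bad_age = (self.age < AGE_MIN) | (self.age > AGE_MAX)
        if bad_age.any():
            i = int(np.nonzero(bad_age)[0][0])
            raise DomainError(
                f"person {self.ids[i]}: baseline age {self.age[i]} outside "
                f"{AGE_MIN}-{AGE_MAX}"
            )
        if ((self.state < 0) | (self.state >= len(HistoryState))).any():
            raise DomainError("invalid history state code in cohort")
        if ((self.sex_idx < 0) | (self.sex_idx >= len(SEXES))).any():
            raise DomainError("invalid sex code in cohort")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_persons(self) -> int:
        return len(self)

    @classmethod
    def from_persons(
        cls, persons: Iterable[Person], baseline_year: int = 2001
    ) -> "BaselineCohort":
        persons = list(persons)
        return cls(
            ids=[p.id for p in persons],
            sex_idx=np.array([sex_index(p.sex) for p in persons]),
            age=np.array([p.age for p in persons]),
            state=np.array([int(p.state) for p in persons]),
            baseline_year=baseline_year,
        )

    def persons(self) -> list[Person]:
        """Record-oriented copy (each call builds fresh Person objects)."""
        return [
            Person(
                id=self.ids[i],
                sex=SEXES[self.sex_idx[i]],
                age=int(self.age[i]),
                state=HistoryState(int(self.state[i])),
            )
            for i in range(len(self))
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": np.asarray(SEXES)[self.sex_idx],
                "age": self.age,
                "state": [HistoryState(int(s)).name for s in self.state],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, baseline_year: int = 2001) -> "BaselineCohort":
        missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"cohort missing columns: {sorted(missing)}")
        ids, sexes, ages, states = [], [], [], []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                ids.append(str(row.id))
                sexes.append(sex_index(str(row.sex)))
                ages.append(int(row.age))
                states.append(int(parse_state(str(row.state))))
            except (DomainError, ValueError) as exc:
                raise ParseError(f"cohort CSV row {i}: {exc}") from exc
        try:
            return cls(ids, np.array(sexes), np.array(ages), np.array(states),
                       baseline_year=baseline_year)
        except DomainError as exc:
            raise ParseError(str(exc)) from exc

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, baseline_year: int = 2001) -> "BaselineCohort":
        try:
            df = pd.read_csv(path, dtype={"id": str})
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot parse cohort CSV {path}: {exc}") from exc
        return cls.from_frame(df, baseline_year=baseline_year)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BaselineCohort):
            return NotImplemented
        return (
            self.baseline_year == other.baseline_year
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.sex_idx, other.sex_idx)
            and np.array_equal(self.age, other.age)
            and np.array_equal(self.state, other.state)
        )

    def __repr__(self) -> str:
        return f"BaselineCohort(n={len(self)}, baseline_year={self.baseline_year})"


def read_cohort_csv(path: str | Path, baseline_year: int = 2001) -> BaselineCohort:
    return BaselineCohort.read_csv(path, baseline_year=baseline_year)


def write_cohort_csv(cohort: BaselineCohort, path: str | Path) -> None:
    cohort.write_csv(path)
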