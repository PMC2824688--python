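"""Scenario specifications and their application to projected risk tables.

A scenario is an ordered list of modifications of the Base (trend-
extrapolated) risk trajectories.  Two kinds are supported:

``level_off``
    Replace the targeted cells' whole projected trajectory by the fitted
    reference-year (2000) level, held flat.  (A switch selects the raw
    reference-year observation instead of the fitted value.)
``scale``
    Multiply the targeted cells' projected trajectory by a positive
    factor, then clamp to [0, 1].

Modifications default to targeting the no-history state only, which is
how the built-in CHD-incidence scenarios are defined: incident CHD is an
event experienced by people with no prior CHD admission or procedure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .errors import ConfigError, TableValidationError
from .risks import AnnualRiskTable
from .states import AGE_BANDS, EventType, HistoryState, SEXES
from .trends import TrendSurface

__all__ = [
    "Modification",
    "ScenarioSpec",
    "apply_scenario",
    "builtin_scenarios",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Modification:
    """One declarative change to a set of projected risk trajectories."""

    events: tuple[EventType, ...]
    kind: str  # "level_off" | "scale"
    factor: float | None = None
    states: tuple[HistoryState, ...] = (HistoryState.NO_HISTORY,)
    sexes: tuple[str, ...] | None = None  # None = both
    age_bands: tuple[str, ...] | None = None  # None = all

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(EventType(e) for e in self.events))
        object.__setattr__(self, "states", tuple(HistoryState(s) for s in self.states))
        if not self.events:
            raise ConfigError("modification targets no events")
        if self.kind == "scale":
            if self.factor is None or self.factor <= 0:
                raise ConfigError(f"scale modification needs factor > 0, got {self.factor}")
        elif self.kind == "level_off":
            pass  # factor ignored
        else:
            raise ConfigError(f"unknown modification kind {self.kind!r}")
        if self.sexes is not None:
            bad = set(self.sexes) - set(SEXES)
            if bad:
                raise ConfigError(f"unknown sex filter {sorted(bad)}")
        if self.age_bands is not None:
            bad = set(self.age_bands) - set(AGE_BANDS)
            if bad:
                raise ConfigError(f"unknown age-band filter {sorted(bad)}")

    def mask(self) -> np.ndarray:
        """Boolean cell mask of shape (2, 9, 4, 5) selecting the targets."""
        m = np.zeros(TrendSurface.SHAPE, dtype=bool)
        si = ([SEXES.index(s) for s in self.sexes]
              if self.sexes is not None else list(range(len(SEXES))))
        bi = ([AGE_BANDS.index(b) for b in self.age_bands]
              if self.age_bands is not None else list(range(len(AGE_BANDS))))
        sti = [int(s) for s in self.states]
        evi = [int(e) for e in self.events]
        m[np.ix_(si, bi, sti, evi)] = True
        return m

    def to_dict(self) -> dict:
        d: dict = {
            "events": [e.name for e in self.events],
            "states": [s.name for s in self.states],
            "kind": self.kind,
        }
        if self.kind == "scale":
            d["factor"] = self.factor
        if self.sexes is not None:
            d["sexes"] = list(self.sexes)
        if self.age_bands is not None:
            d["age_bands"] = list(self.age_bands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Modification":
        try:
            return cls(
                events=tuple(EventType[e] for e in d["events"]),
                kind=d["kind"],
                factor=d.get("factor"),
                states=tuple(HistoryState[s] for s in d.get("states", ["NO_HISTORY"])),
                sexes=tuple(d["sexes"]) if "sexes" in d else None,
                age_bands=tuple(d["age_bands"]) if "age_bands" in d else None,
            )
        except KeyError as exc:
            raise ConfigError(f"bad modification spec {d!r}: {exc}") from exc


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """A named, ordered list of modifications; empty list = Base scenario."""

    name: str
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifications", tuple(self.modifications))

    @property
    def is_base(self) -> bool:
        return not self.modifications

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name,
             "modifications": [m.to_dict() for m in self.modifications]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"bad scenario JSON: {exc}") from exc
        if "name" not in d:
            raise ConfigError("scenario JSON missing 'name'")
        return cls(
            name=str(d["name"]),
            modifications=tuple(
                Modification.from_dict(m) for m in d.get("modifications", [])
            ),
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_json(Path(path).read_text())

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def apply_scenario(
    projected: AnnualRiskTable,
    trends: TrendSurface,
    spec: ScenarioSpec,
    level_off_at: str = "fitted",
) -> AnnualRiskTable:
    """Apply a scenario's modifications to a Base-projected risk table.

    ``level_off`` replaces every projected year of a targeted cell by the
    trend's reference-year level (fitted by default, the raw observation
    with ``level_off_at="observed"``); ``scale`` multiplies the projected
    trajectory and clamps to [0, 1].  Untargeted cells are returned
    bit-identical.  The modified table must still satisfy the
    competing-risk-sum invariant.
    """
    if level_off_at == "fitted":
        level = trends.level_probability()
    elif level_off_at == "observed":
        if trends.observed is None:
            raise ConfigError("trend surface carries no observed levels")
        level = np.clip(trends.observed, 0.0, 1.0)
    else:
        raise ConfigError(f"unknown level_off_at {level_off_at!r}")

    out = projected.copy()
    for mod in spec.modifications:
        m = mod.mask()
        if mod.kind == "level_off":
            out.values[:, m] = level[m]
        else:  # scale
            scaled = out.values[:, m] * mod.factor
            clipped = np.clip(scaled, 0.0, 1.0)
            n_clamped = int((clipped != scaled).sum())
            if n_clamped:
                logger.info(
                    "scenario %s: scaling by %g clamped %d cell-years to [0,1]",
                    spec.name, mod.factor, n_clamped,
                )
            out.values[:, m] = clipped
    sum_violations = [v for v in out.validate() if "sum exceeds" in v]
    if sum_violations:
        raise TableValidationError(sum_violations)
    return out


def builtin_scenarios() -> list[ScenarioSpec]:
    """The five built-in CHD-incidence scenarios.

    Base continues all fitted 1998-2000 trends unchanged through the
    projection horizon.  The incidence scenarios perturb incident-CHD
    risks (events experienced in the no-history state): (1) levels off
    the CHD-admission risk; (2)/(3) scale it by 1.10/1.20; (4) combines a
    20% CHD-admission increase, a 5% PCI increase and level-offs of the
    CABG and CHD-death risks.
    """
    adm = (EventType.CHD_ADMISSION_NO_CARP,)
    return [
        ScenarioSpec("base"),
        ScenarioSpec("incidence1", (
            Modification(events=adm, kind="level_off"),
        )),
        ScenarioSpec("incidence2", (
            Modification(events=adm, kind="scale", factor=1.10),
        )),
        ScenarioSpec("incidence3", (
            Modification(events=adm, kind="scale", factor=1.20),
        )),
        ScenarioSpec("incidence4", (
            Modification(events=adm, kind="scale", factor=1.20),
            Modification(events=(EventType.PCI,), kind="scale", factor=1.05),
            Modification(events=(EventType.CABG,), kind="level_off"),
            Modification(events=(EventType.CHD_DEATH,), kind="level_off"),
        )),
    ]


def builtin_scenario(name: str) -> ScenarioSpec:
    for spec in builtin_scenarios():
        if spec.name == name:
            return spec
    raise ConfigError(f"unknown built-in scenario {name!r}")
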