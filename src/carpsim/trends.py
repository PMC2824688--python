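"""Linear trend fitting and projection of annual event risks.

Each (sex, age band, state, event) cell of the historical risk table gets
its own straight line fitted by ordinary least squares through the
observation window (1998-2000 by default).  The fitted line is
parameterised by its value at the reference year (the last year of the
window) and its slope in probability units per calendar year; projected
values for future years are clamped to [floor, cap].

Fitting is done on the probability scale by default.  A logit-scale
option is available: the line is fitted to logit(p) and back-transformed
at projection time, which keeps projections inside (0, 1) without
clamping.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DomainError, TableValidationError
from .risks import AnnualRiskTable
from .states import (
    AGE_BANDS,
    EventType,
    HistoryState,
    N_BANDS,
    N_EVENTS,
    N_SEXES,
    N_STATES,
    SEXES,
)

__all__ = ["LinearTrend", "TrendSurface", "fit_linear_trend", "project_risks"]

logger = logging.getLogger(__name__)

#: Probabilities are pulled this far inside (0, 1) before taking logits.
_LOGIT_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class LinearTrend:
    """A fitted per-cell risk trend.

    ``level`` is the fitted value at ``reference_year`` (not the raw
    observation there); ``slope`` is change per calendar year, both on the
    fitting scale.  ``observed_level`` keeps the raw reference-year
    observation (probability scale) for the level-off-at-observed option.
    """

    reference_year: int
    level: float
    slope: float
    observed_level: float | None = None
    scale: str = "probability"

    def predict(self, year: int | np.ndarray) -> float | np.ndarray:
        """Unclamped fitted value at *year*, on the probability scale."""
        raw = self.level + self.slope * (np.asarray(year) - self.reference_year)
        return expit(raw) if self.scale == "logit" else raw

    @property
    def level_probability(self) -> float:
        """The fitted reference-year value on the probability scale."""
        return float(expit(self.level)) if self.scale == "logit" else self.level


def fit_linear_trend(
    observations: Iterable[tuple[int, float]],
    years: Sequence[int] = (1998, 1999, 2000),
    method: str = "ols",
    scale: str = "probability",
) -> LinearTrend:
    """Fit a straight line to one cell's (year, probability) observations.

    Parameters
    ----------
    observations
        One (year, probability) pair per year of the fitting window.
    years
        The required observation years; the reference year is the last.
    method
        ``"ols"`` (least squares through all points, the default) or
        ``"endpoints"`` (slope from the first and last observation, level
        equal to the raw last observation).
    """
    obs = dict(observations)
    years = sorted(years)
    missing = set(years) - set(obs)
    if missing:
        raise DomainError(f"missing observation year(s) {sorted(missing)}")
    extra = set(obs) - set(years)
    if extra:
        raise DomainError(f"unexpected observation year(s) {sorted(extra)}")
    y = np.array([obs[t] for t in years], dtype=float)
    if ((y < 0.0) | (y > 1.0)).any():
        raise DomainError(f"probability outside [0,1] in observations {obs}")
    ref = years[-1]
    if scale == "logit":
        y = logit(np.clip(y, _LOGIT_EPS, 1.0 - _LOGIT_EPS))
    elif scale != "probability":
        raise DomainError(f"unknown fitting scale {scale!r}")
    x = np.asarray(years, dtype=float)
    observed = float(obs[ref])
    if method == "endpoints":
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        level = float(y[-1])
    elif method == "ols":
        xc = x - x.mean()
        slope = float((xc * (y - y.mean())).sum() / (xc * xc).sum())
        level = float(y.mean() + slope * (ref - x.mean()))
    else:
        raise DomainError(f"unknown trend-fit method {method!r}")
    return LinearTrend(reference_year=ref, level=level, slope=float(slope),
                       observed_level=observed, scale=scale)


class TrendSurface:
    """Per-cell linear trends for every (sex, band, state, event) cell.

    A vectorised container for the full grid of :class:`LinearTrend`
    values: ``level``, ``slope`` and ``observed`` are arrays of shape
    ``(2, 9, 4, 5)``.
    """

    SHAPE = (N_SEXES, N_BANDS, N_STATES, N_EVENTS)

    def __init__(
        self,
        reference_year: int,
        level: np.ndarray,
        slope: np.ndarray,
        observed: np.ndarray | None = None,
        slope_se: np.ndarray | None = None,
        scale: str = "probability",
    ):
        self.reference_year = int(reference_year)
        self.level = np.asarray(level, dtype=float)
        self.slope = np.asarray(slope, dtype=float)
        self.observed = None if observed is None else np.asarray(observed, dtype=float)
        self.slope_se = None if slope_se is None else np.asarray(slope_se, dtype=float)
        self.scale = scale
        for arr in (self.level, self.slope):
            if arr.shape != self.SHAPE:
                raise DomainError(f"trend array shape {arr.shape} != {self.SHAPE}")

    @classmethod
    def from_table(
        cls,
        history: AnnualRiskTable,
        fit_years: Sequence[int] = (1998, 1999, 2000),
        method: str = "ols",
        scale: str = "probability",
    ) -> "TrendSurface":
        """Fit every cell's trend from a historical risk table.

        The closed-form OLS solution is evaluated for all cells at once;
        it matches :func:`fit_linear_trend` cell by cell.
        """
        fit_years = sorted(fit_years)
        if len(fit_years) < 2:
            raise DomainError("need at least two years to fit a trend")
        ref = fit_years[-1]
        idx = [history.year_index(t) for t in fit_years]
        y = history.values[idx]  # (n_fit_years, 2, 9, 4, 5)
        if np.isnan(y).any():
            raise TableValidationError(
                ["missing cells in the trend-fitting window "
                 f"{fit_years[0]}-{fit_years[-1]}"]
            )
        observed = y[-1].copy()
        if scale == "logit":
            y = logit(np.clip(y, _LOGIT_EPS, 1.0 - _LOGIT_EPS))
        x = np.asarray(fit_years, dtype=float).reshape(-1, 1, 1, 1, 1)
        if method == "endpoints":
            slope = (y[-1] - y[0]) / float(fit_years[-1] - fit_years[0])
            level = y[-1].copy()
            slope_se = np.full(slope.shape, np.nan)
        elif method == "ols":
            xc = x - x.mean()
            sxx = float((xc ** 2).sum())
            slope = (xc * (y - y.mean(axis=0))).sum(axis=0) / sxx
            level = y.mean(axis=0) + slope * (ref - x.mean())
            fitted = y.mean(axis=0) + slope * xc
            rss = ((y - fitted) ** 2).sum(axis=0)
            df = len(fit_years) - 2
            with np.errstate(divide="ignore", invalid="ignore"):
                slope_se = np.sqrt(rss / df / sxx) if df > 0 else np.full(slope.shape, np.nan)
        else:
            raise DomainError(f"unknown trend-fit method {method!r}")
        return cls(ref, level, slope, observed=observed, slope_se=slope_se, scale=scale)

    # -- projection ----------------------------------------------------

    def level_probability(self) -> np.ndarray:
        """Fitted reference-year values on the probability scale."""
        lvl = expit(self.level) if self.scale == "logit" else self.level
        return np.clip(lvl, 0.0, 1.0)

    def project(
        self,
        start_year: int = 2001,
        end_year: int = 2010,
        floor: float = 0.0,
        cap: float = 1.0,
    ) -> AnnualRiskTable:
        """Extrapolate every cell's line over [start_year, end_year].

        Values are clamped to [floor, cap]; clamping events are logged
        with cell identity.  The projected table must satisfy the
        competing-risk-sum invariant or a :class:`TableValidationError`
        listing the offending cells is raised.
        """
        if not (0.0 <= floor <= cap <= 1.0):
            raise DomainError(f"need 0 <= floor <= cap <= 1, got {floor}, {cap}")
        dx = np.arange(start_year, end_year + 1) - self.reference_year
        raw = self.level[None] + self.slope[None] * dx.reshape(-1, 1, 1, 1, 1)
        if self.scale == "logit":
            raw = expit(raw)
        clamped = np.clip(raw, floor, cap)
        n_clamped = int((clamped != raw).sum())
        if n_clamped:
            yi, si, bi, sti, ei = np.nonzero(clamped != raw)
            logger.info(
                "projection clamped %d cell-years to [%g, %g]; first: "
                "(year=%d, sex=%s, age_band=%s, state=%s, event=%s)",
                n_clamped, floor, cap, start_year + yi[0], SEXES[si[0]],
                AGE_BANDS[bi[0]], HistoryState(sti[0]).name, EventType(ei[0]).name,
            )
        table = AnnualRiskTable(start_year, end_year, clamped)
        sum_violations = [v for v in table.validate() if "sum exceeds" in v]
        if sum_violations:
            raise TableValidationError(sum_violations)
        return table

    # -- (de)serialisation ----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        si, bi, sti, ei = np.indices(self.SHAPE).reshape(4, -1)
        return pd.DataFrame(
            {
                "sex": np.asarray(SEXES)[si],
                "age_band": np.asarray(AGE_BANDS)[bi],
                "state": [HistoryState(k).name for k in sti],
                "event": [EventType(k).name for k in ei],
                "level": self.level.ravel(),
                "slope": self.slope.ravel(),
                "observed_level": (np.full(si.shape, np.nan)
                                   if self.observed is None else self.observed.ravel()),
                "reference_year": self.reference_year,
                "scale": self.scale,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrendSurface":
        df = pd.read_csv(path, float_precision="round_trip")
        ref = int(df["reference_year"].iloc[0])
        scale = str(df["scale"].iloc[0])
        level = np.full(cls.SHAPE, np.nan)
        slope = np.full(cls.SHAPE, np.nan)
        observed = np.full(cls.SHAPE, np.nan)
        for row in df.itertuples(index=False):
            key = (
                SEXES.index(row.sex),
                AGE_BANDS.index(row.age_band),
                int(HistoryState[row.state]),
                int(EventType[row.event]),
            )
            level[key] = row.level
            slope[key] = row.slope
            observed[key] = row.observed_level
        return cls(ref, level, slope, observed=observed, scale=scale)

    def cell(self, sex: str, age_band: str, state: HistoryState,
             event: EventType) -> LinearTrend:
        """The scalar :class:`LinearTrend` for one cell."""
        key = (SEXES.index(sex), AGE_BANDS.index(age_band), int(state), int(event))
        return LinearTrend(
            reference_year=self.reference_year,
            level=float(self.level[key]),
            slope=float(self.slope[key]),
            observed_level=None if self.observed is None else float(self.observed[key]),
            scale=self.scale,
        )


def project_risks(
    trends: TrendSurface,
    start_year: int = 2001,
    end_year: int = 2010,
    floor: float = 0.0,
    cap: float = 1.0,
) -> AnnualRiskTable:
    """Functional form of :meth:`TrendSurface.project`."""
    return trends.project(start_year, end_year, floor=floor, cap=cap)
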