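"""Synthetic baseline cohorts and historical risk tables.

The real model inputs — a population cohort classified into CHD/CARP
history states from two decades of linked hospital records, and annual
event risks estimated from the same records — are not publicly
available.  This module generates stand-ins with the qualitative
structure the analysis assumes:

* risks of CHD admission, CABG and CHD death decline over calendar time
  while the PCI risk rises;
* risks increase with age, are higher in males and (for CHD-related
  events) higher in people with a CHD/CARP history;
* the CHD-admission-without-procedure risk is the dominant (largest)
  component of incident CHD in every stratum;
* history-state prevalence at baseline rises with age.

Every probability is produced through an inverse-logit link,

    p = expit(alpha_e + beta_age*(age_mid - 55) + beta_male*[male]
              + state_effect + gamma_e*(year - 2000) + noise),

so values stay inside (0, 1) by construction; observation noise is
applied on the logit scale.  The default coefficients are calibrated
only to the qualitative statements above — they are not estimates of
any real population's risks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort import BaselineCohort
from .errors import ConfigError
from .risks import AnnualRiskTable
from .states import (
    AGE_BAND_MIDPOINTS,
    EventType,
    HistoryState,
    N_BANDS,
    N_EVENTS,
    N_STATES,
)

__all__ = ["SyntheticConfig", "generate_cohort", "generate_risk_history"]

#: Per-event logit intercepts: risk at (female, age-band midpoint 55,
#: no history, year 2000).  Offsets keep CHD admission the dominant
#: incident-CHD component in every cell.
DEFAULT_ALPHA = {
    EventType.CHD_ADMISSION_NO_CARP: -5.3,
    EventType.CABG: -7.4,
    EventType.PCI: -7.1,
    EventType.CHD_DEATH: -6.6,
    EventType.NON_CHD_DEATH: -5.5,
}

#: Per-event calendar slopes (logit units per year): everything declines
#: except the PCI risk.
DEFAULT_GAMMA = {
    EventType.CHD_ADMISSION_NO_CARP: -0.03,
    EventType.CABG: -0.05,
    EventType.PCI: +0.06,
    EventType.CHD_DEATH: -0.04,
    EventType.NON_CHD_DEATH: -0.01,
}

#: Additive logit effect of history state, applied to CHD-related events
#: only (non-CHD death does not depend on CHD history here).
DEFAULT_STATE_EFFECT = {
    HistoryState.NO_HISTORY: 0.0,
    HistoryState.CHD_NO_CARP: 1.5,
    HistoryState.PCI_NO_CABG: 1.8,
    HistoryState.CABG_HISTORY: 2.0,
}


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort and risk generators."""

    n_persons: int = 10_000
    proportion_male: float = 0.5
    #: Relative weight of each 5-year band, 35-39 first; default declines
    #: linearly to the oldest band.
    age_band_weights: tuple[float, ...] = tuple(
        float(w) for w in range(N_BANDS, 0, -1)
    )
    #: P(any CHD/CARP history | age) = expit(a0 + a1 * age).
    history_a0: float = -6.0
    history_a1: float = 0.07
    #: Split of history mass across the three history states.
    history_split: dict = dataclasses.field(
        default_factory=lambda: {
            HistoryState.CHD_NO_CARP: 0.5,
            HistoryState.PCI_NO_CABG: 0.3,
            HistoryState.CABG_HISTORY: 0.2,
        }
    )
    alpha: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta_age: float = 0.08  # logit units per year of age
    beta_male: float = 0.5
    state_effect: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STATE_EFFECT)
    )
    gamma: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_GAMMA))
    noise_sd: float = 0.02  # observation noise, logit scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigError(f"n_persons must be >= 1, got {self.n_persons}")
        if not (0.0 <= self.proportion_male <= 1.0):
            raise ConfigError(f"proportion_male {self.proportion_male} outside [0,1]")
        w = np.asarray(self.age_band_weights, dtype=float)
        if len(w) != N_BANDS or (w < 0).any() or w.sum() <= 0:
            raise ConfigError("age_band_weights must be 9 non-negative weights")
        split = {HistoryState(k): float(v) for k, v in self.history_split.items()}
        if set(split) != {HistoryState.CHD_NO_CARP, HistoryState.PCI_NO_CABG,
                          HistoryState.CABG_HISTORY}:
            raise ConfigError("history_split must cover the three history states")
        if any(v < 0 for v in split.values()) or abs(sum(split.values()) - 1.0) > 1e-9:
            raise ConfigError("history_split must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        self.history_split = split
        self.alpha = {EventType(k): float(v) for k, v in self.alpha.items()}
        self.gamma = {EventType(k): float(v) for k, v in self.gamma.items()}
        self.state_effect = {HistoryState(k): float(v)
                             for k, v in self.state_effect.items()}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["history_split"] = {k.name: v for k, v in self.history_split.items()}
        d["alpha"] = {k.name: v for k, v in self.alpha.items()}
        d["gamma"] = {k.name: v for k, v in self.gamma.items()}
        d["state_effect"] = {k.name: v for k, v in self.state_effect.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        for field, enum_cls in (("history_split", HistoryState), ("alpha", EventType),
                                ("gamma", EventType), ("state_effect", HistoryState)):
            if field in d:
                d[field] = {enum_cls[k]: v for k, v in d[field].items()}
        if "age_band_weights" in d:
            d["age_band_weights"] = tuple(d["age_band_weights"])
        return cls(**d)

    @classmethod
    def read_json(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_json(Path(path).read_text())


def generate_cohort(config: SyntheticConfig | None = None) -> BaselineCohort:
    """Draw a seeded, reproducible baseline cohort.

    Ages are drawn band-first (config weights) then uniformly within the
    band; P(any history | age) follows the configured logistic curve and
    history mass is split across the three history states.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_persons

    w = np.asarray(config.age_band_weights, dtype=float)
    band = rng.choice(N_BANDS, size=n, p=w / w.sum())
    age = 35 + 5 * band + rng.integers(0, 5, size=n)
    sex_idx = (rng.random(n) >= config.proportion_male).astype(np.int64)  # 0 = male

    p_hist = expit(config.history_a0 + config.history_a1 * age)
    has_hist = rng.random(n) < p_hist
    split_states = np.array([int(HistoryState.CHD_NO_CARP),
                             int(HistoryState.PCI_NO_CABG),
                             int(HistoryState.CABG_HISTORY)])
    split_p = np.array([config.history_split[HistoryState(s)] for s in split_states])
    state = np.zeros(n, dtype=np.int64)
    state[has_hist] = rng.choice(split_states, size=int(has_hist.sum()), p=split_p)

    ids = [f"p{i:07d}" for i in range(n)]
    return BaselineCohort(ids, sex_idx, age, state, baseline_year=2001)


def _logit_surface(config: SyntheticConfig, years: np.ndarray) -> np.ndarray:
    """Noise-free logit of every (year, sex, band, state, event) cell."""
    alpha = np.array([config.alpha[EventType(e)] for e in range(N_EVENTS)])
    gamma = np.array([config.gamma[EventType(e)] for e in range(N_EVENTS)])
    state_eff = np.array([config.state_effect[HistoryState(s)]
                          for s in range(N_STATES)])
    mid = np.asarray(AGE_BAND_MIDPOINTS)
    # logit[y, s, b, st, e]
    lg = (
        alpha[None, None, None, None, :]
        + config.beta_age * (mid[None, None, :, None, None] - 55.0)
        + config.beta_male * (np.array([1.0, 0.0])[None, :, None, None, None])
        + gamma[None, None, None, None, :] * (years[:, None, None, None, None] - 2000.0)
    )
    # history effect applies to CHD-related events only
    chd_related = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
    lg = lg + state_eff[None, None, None, :, None] * chd_related[None, None, None, None, :]
    return lg


def generate_risk_history(
    config: SyntheticConfig | None = None,
    start_year: int = 1990,
    end_year: int = 2000,
) -> AnnualRiskTable:
    """Generate a complete historical risk table over the given years.

    With ``noise_sd = 0`` the generator is deterministic and equals the
    configured logistic formula exactly.  Competing-risk sums exceeding 1
    raise a :class:`ConfigError` advising smaller intercepts.
    """
    config = config or SyntheticConfig()
    if end_year < start_year:
        raise ConfigError("end_year before start_year")
    years = np.arange(start_year, end_year + 1)
    lg = _logit_surface(config, years)
    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        lg = lg + rng.normal(0.0, config.noise_sd, size=lg.shape)
    table = AnnualRiskTable(start_year, end_year, expit(lg))
    bad = [v for v in table.validate() if "sum exceeds" in v]
    if bad:
        raise ConfigError(
            "synthetic risks violate the competing-risk-sum invariant; "
            f"use smaller intercepts: {bad[0]}"
        )
    return table
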