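# Methods

## Model structure

`carpsim` simulates a closed cohort through a discrete-time (annual)
multi-state process. The state space is the four CHD/CARP history
states, ordered by dominance (`NO_HISTORY < CHD_NO_CARP < PCI_NO_CABG <
CABG_HISTORY`); a person's state never moves down this order — a CABG
ever performed dominates any number of PCIs, which dominate a bare CHD
admission. Five annual events drive transitions: CHD admission without
a procedure, CABG, PCI, CHD death and non-CHD death. The five event
probabilities of a (year, sex, age band, state) cell are competing
risks whose sum must not exceed 1; the residual mass is "no event this
year". Tables violating the sum constraint are rejected, never
renormalized, because silent renormalization would hide input errors.

### Within-year sub-cycle

The within-year rule allows one CHD admission without a CARP, up to two
admissions with CARPs, and death:

1. one categorical draw over the five events + "none" at the current
   state's risks;
2. either death terminates the person; mortality acts once per year and
   is not re-drawn after a procedure (re-drawing would double-count the
   annual death risk);
3. an admission updates the state (`NO_HISTORY → CHD_NO_CARP`) and
   permits one follow-on draw over {CABG, PCI, none};
4. a CARP updates the state immediately (follow-on draws therefore use
   the *new* state's risks — the only reading under which a follow-on
   draw is well defined for a person whose first-ever event was a
   procedure) and permits one follow-on draw;
5. after the second CARP the year ends; a year therefore records at
   most three events (admission + two procedures).

The exact ordering of recognised events within a cycle is a genuinely
open design point; this rule is the most parsimonious one consistent
with the event-count allowances above, and it is isolated behind
`simulate_person_year` / `expectation._sub_cycle_tree` so an alternative
can be swapped in one place.

### Ageing and censoring

Ages are single integer years; risks are stored by 5-year band and
looked up at attained age, so persons cross bands as they age.
Survivors age at year end; reaching 80 removes the person (aged out).
Conservation — alive + died + aged out = baseline cohort size — holds
exactly in every replicate and to 1e-9 in expectation.

## Trend fitting and projection

Each of the 360 risk cells gets its own straight line through the
fitting window (default 1998–2000), by closed-form OLS on centered
years. The trend is parameterised by `level` (the *fitted* value at the
reference year, the window's last year) and `slope` (probability per
calendar year); with three equally spaced years the OLS slope reduces
to the endpoint slope (y₂₀₀₀ − y₁₉₉₈)/2, but the fitted level differs
from the raw 2000 observation. OLS slope standard errors (1 residual
df for a 3-point window) are reported in `params` for descriptive use.

Projection evaluates the line over the horizon and clamps to
[floor, cap] (defaults 0 and 1); clamping events are logged with cell
identity, and a projected table whose competing sums exceed 1 raises an
error listing the offending cells. Choices that were genuinely open:

* **Scale of fitting.** Default is the probability scale ("linear trend
  in event risks" read literally), with clamping handling boundary
  violations; `scale="logit"` fits the line to logit(p) and
  back-transforms, keeping projections strictly inside (0, 1).
* **Endpoint alternative.** Whether the original trend used least
  squares or endpoints is unknowable; both are implemented
  (`method="ols"` default, `"endpoints"`).
* **What "level off" holds flat.** Default is the fitted reference-year
  value (consistent with using the fitted line everywhere else);
  `level_off_at="observed"` holds the raw 2000 observation instead.
* **What scaling multiplies.** A `scale` modification multiplies the
  *trend-projected* trajectory, not a flattened 2000 level — "increased
  by 10% while the trends continue" read as a perturbation of the Base
  projection. The level-off machinery composes with scaling for anyone
  wanting the other reading.

## Scenarios

A scenario is an ordered list of declarative modifications (`level_off`
or `scale`, with event/state/sex/age-band filters defaulting to the
no-history state, where incident CHD lives). The five built-ins are
`base` (no modifications) and `incidence1`–`incidence4` as documented
in the README. Modified tables are re-validated; untargeted cells are
bit-identical to the Base projection.

## Randomness and reproducibility

One named master seed controls everything. Replicate `r` draws its
generator from the `r`-th spawn of `numpy.random.SeedSequence(seed)`.
Within a replicate the cohort engine consumes exactly three uniforms
per baseline person per year in fixed person order — whether or not the
person is still active — so each person's draws depend only on
(seed, replicate, year, person index). Consequences: results are
bit-reproducible regardless of batching, and scenarios run under one
master seed share common random numbers — their event streams differ
only where modified risks flip a draw, so an all-identity scenario is
bit-identical to Base and scenario contrasts carry no between-stream
Monte Carlo noise. An independent-seeds mode offsets the master seed
per scenario for anyone who wants uncorrelated runs.

The scalar reference implementation (`simulate_person_year`) draws
lazily (one uniform per draw made) and is therefore not stream-aligned
with the vectorised engine; both are checked against the expectation
oracle rather than against each other's streams.

## The expectation oracle

`expected_counts` propagates probability mass over (sex, attained age,
state) strata, enumerating per person-year the full outcome tree of the
same sub-cycle rule (≤ 54 potential draw paths collapse to ~17 reachable
branches). Because the rule is enumerated exactly rather than
approximated by a transition matrix, the stochastic engine's replicate
averages converge to the oracle's counts with no discretisation gap,
which is what makes the 5-standard-error engine/oracle agreement test a
sharp check. The test suite additionally verifies the oracle itself
against an independently coded exhaustive path enumeration on small
cohorts (agreement to 1e-12) and against closed forms (survival ×
hazard chains; p·T total for a constant non-absorbing risk).

## Synthetic data

The generator stands in for inputs estimated from linked
hospital-admission records, which are not publicly available. It is
calibrated only to qualitative structure, not to any real population's
risks, and says so here rather than pretending fidelity.

Every probability comes from an inverse-logit linear predictor

    logit p = α_e + β_age (age_mid − 55) + β_male·[male] + s_state
              + γ_e (year − 2000) + ε,     ε ~ N(0, σ²) on the logit scale

so values lie in (0, 1) by construction. Defaults:

| parameter | value | meaning |
|---|---|---|
| `n_persons` | 10 000 | cohort size (tractable desk scale; tests and the acceptance run use it) |
| `proportion_male` | 0.5 | sex mix |
| band weights | 9, 8, …, 1 | age pyramid declining linearly from band 35–39 to 75–79 |
| `history_a0`, `history_a1` | −6.0, 0.07 | P(any history \| age) = expit(a0 + a1·age); ≈4% at 40, ≈32% at 75 |
| history split | 0.5 / 0.3 / 0.2 | CHD-no-CARP / PCI-no-CABG / CABG-history |
| α (admission, CABG, PCI, CHD death, non-CHD death) | −5.3, −7.4, −7.1, −6.6, −5.5 | logit risk at (female, age-mid 55, no history, 2000): ≈0.005, 0.0006, 0.0008, 0.0014, 0.004 |
| `beta_age` | 0.08 /yr | risks rise with age |
| `beta_male` | 0.5 | risks higher in males |
| state effects | 0 / 1.5 / 1.8 / 2.0 | higher CHD-related risks with history (not applied to non-CHD death) |
| γ (per year) | −0.03, −0.05, +0.06, −0.04, −0.01 | everything declines except the PCI risk |
| `noise_sd` | 0.02 | year-to-year observation noise, logit scale |

The intercept offsets make the CHD-admission risk the dominant incident
component in every cell and every year (α difference 2.1 logits against
CABG, shrinking by only 0.02/yr backwards in time), and the worst-case
competing sum (male, 75–79, CABG history, 1990) stays near 0.6, well
inside the sum constraint even with noise.

What the generator does **not** emulate: record-linkage errors,
cohort-entry/migration, non-linear age effects, risk-factor covariates
(smoking, blood pressure, obesity, diabetes), correlation between a
person's successive years beyond state, and any calibration to real
incidence levels. Tests passing on these inputs therefore demonstrate
that the machinery — trend fitting, projection, scenario algebra,
simulation, expectation — is correct and internally consistent, not
that its outputs match any particular population's CARP counts.

## Problem sizes and numerical choices

The shipped configuration — 10,000 persons, 10-year horizon, 100
replicates, 360 risk cells — runs the full five-scenario comparison in
a few seconds and keeps every Monte Carlo check well conditioned
(smallest per-year expected event counts ≈ 10, so replicate standard
errors are strictly positive everywhere). Tolerances: competing-sum
validation allows 1e-9 of float slack; oracle mass conservation is
checked to 1e-9 relative; brute-force equivalence to 1e-12; CSV
round-trips are bit-exact (`%.17g` on write, round-trip float parsing
on read). Ties in the categorical draw are impossible for continuous
uniforms; the draw convention assigns outcome k when the uniform falls
in [cum_{k−1}, cum_k), so a certain event (p = 1) is always taken.

## Known limitations

* The within-year ordering is a documented stand-in for an unprinted
  original; different orderings would change third-decimal behaviour of
  within-year procedure chains.
* CHD death competes in the first draw in every state; conditioning CHD
  death on "no CHD admission that year" is a plausible alternative
  reading for the no-history state and is not implemented.
* Trends are per-cell independent straight lines; no smoothing or
  pooling across adjacent bands, no joinpoint or risk-factor-driven
  incidence submodel.
* The cohort is closed: no entry at age 35 and no migration, so
  late-horizon counts understate an open population's demand.
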