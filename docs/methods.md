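# Methods

## Model structure

The model is a discrete-time cohort state-transition (Markov) model
with a 1-year cycle over 26 mutually exclusive health states.  The
decomposition is: `normal` and `death` (2), nine lesion/cancer stages
each split into undetected and detected variants (18) — the esophageal
chain mild dysplasia → moderate dysplasia → severe dysplasia/CIS →
early cancer → advanced cancer and the gastric chain LGIN → HGIN/CIS →
early cancer → advanced cancer — and one posttreatment state per
treatable stage per organ (severe dysplasia/CIS, early, advanced;
HGIN/CIS, early, advanced: 6).  This is the unique decomposition
consistent with splitting every progression state by detection status
and keeping a separate posttreatment tier for the treatable stages.
The builder (`state_space.build_state_space`) is configurable — chains
can be dropped and the treatable set changed — so an alternative
structure can replace the default without touching the engine.

Modelling choices embedded in the structure:

* **Exclusive states.** Simultaneous esophageal and gastric lesions in
  one person are not represented; dual-primary upper-GI cancer is rare
  and cohort models require exclusive states.
* **Detection is irreversible.** No transition may return a detected or
  posttreatment state to an undetected one; `validate_matrix` enforces
  this along with row-stochasticity (tolerance 1e-9), non-negativity
  and an absorbing death state.
* **Detection without treatment does not alter natural history.**
  Detected-untreated states carry the same progression, regression and
  mortality as their undetected counterparts; progression preserves
  the detection flag.

## Within-cycle event order

Screening (when offered) → self-initiated detection → treatment of new
diagnoses → natural-history transition with background mortality.
This order makes a detection and its treatment fall in the same cycle.
Detail per operator:

* **Screening** (`strategies.apply_screening_event`): everyone alive
  and not already detected or posttreatment is invited (mobilization
  cost $1.05 per invitee); 49% attend (endoscopy cost $47.87 per
  attendee).  Attendees with an undetected lesion move to the detected
  state at the organ's sensitivity (EC 0.96, GC 0.89).  Screen-found
  mild/moderate dysplasia and LGIN enter the detected state — an
  annual-surveillance tier — only for the reexamination-compliant
  fraction (0.67); the remainder stays undetected.  This gating is how
  the model realizes surveillance drop-out without violating
  detection irreversibility, and it is equivalent in expectation to
  detecting first and losing the non-compliant to follow-up.
  Surveillance costs one endoscopy per person-year, and progression
  under surveillance stays detected.  Attendees without disease in an
  organ yield a false positive at 1 − specificity (EC 0.90, GC 1.00;
  combined for the fully healthy), each costing one reexamination
  endoscopy and a utility decrement (default 0.001 QALY, configurable
  — no published magnitude exists).  Complications occur at 9 × 10⁻⁵
  per attendee and cost $113.68.
* **Self-detection** (`apply_self_detection`), every cycle, moves
  undetected mass to detected at annual probabilities 0.01 (severe
  dysplasia/CIS and HGIN/CIS), 0.20 (early cancer), 0.70 (advanced
  cancer).  Low-grade lesions are asymptomatic and never self-detect.
* **Treatment** (`apply_treatment`) applies the stage-specific
  compliance (0.7458, 0.9405, 0.9643, 0.5455, 0.9000, 0.9643 for
  EC severe/early/advanced and GC HGIN/early/advanced) to *newly*
  diagnosed mass, moving it to posttreatment and charging the initial
  treatment cost.  Non-compliant mass remains detected-untreated
  permanently.  Mass that arrives in a detected treatable state
  through the transition matrix — surveillance progression to
  severe/HGIN, progression of detected untreated early cancer to
  advanced, recurrence from posttreatment — is a new diagnosis and is
  offered treatment at the next cycle's treatment step.
* **Transition**: the annual matrix with the age-specific background
  death probability overlaid by proportional rescaling (non-death
  entries shrink by 1 − q, rows stay stochastic), so background and
  disease-specific mortality compete.

## Screening schedules

Rounds start at cycle 0 and repeat every *k* years while the cohort's
mean age is at most 69 (the eligibility window is 40–69, which
reproduces exactly which strategy rows are distinct per age band:
every-10-years collapses onto once-per-lifetime from mean age 62, and
only once and every-2-years remain distinct at 67).  Compliance is
assumed identical and independent at every round; posttreatment and
already-detected people leave the invitation pool.

## Rewards, discounting, half-cycle correction

State rewards use the trapezoidal half-cycle correction: the average
of start- and end-of-cycle occupancy multiplies the per-state utility
and annual care cost.  For constant occupancy this reduces to exact
person-years, which is the identity the tests assert.  One-time event
costs and disutilities are discounted at mid-cycle, (1+r)^−(t+0.5),
consistent with events spread through the year; a cycle-start
convention is available via `event_timing="start"` since tool defaults
differ on this point.  State rewards use the same mid-cycle factor.
The base-case discount rate is 5% (sweep range 0–8%) for both QALYs
and costs.  Utilities are stage-level (advanced GC 0.57 … mild
dysplasia 1.00); detection and posttreatment status do not change a
stage's utility, and annual care costs accrue only in care (detected
severe/HGIN, detected cancer, posttreatment) — the stage-level
published figures are applied to all in-care variants because the
per-state breakdown is not published in full detail.

## Cost-effectiveness comparison

`cea.frontier_sequence` orders strategies by effectiveness and
compares each with its predecessor.  The default *sequential* mode
performs no dominance pruning — the published base-case table reports
a non-monotone ICER sequence (3035 then 1087 $/QALY in the youngest
band), which proves no pruning was done there — while *frontier* mode
applies standard strict- and extended-dominance elimination, leaving
strictly increasing ICERs.  ICERs are reported rounded to whole
dollars (halves away from zero); increments are carried at full
precision internally.  WHO thresholds classify an ICER as highly
cost-effective below 1× per-capita GDP ($10 276), cost-effective from
1× to 3×, and not cost-effective above 3×.

## Uncertainty analysis

Every parameter carries a `DistributionSpec`: triangular
(min, mode, max), beta (shape1, shape2), gamma (shape, rate) or fixed,
plus a (low, high) range for one-way sweeps.  Gamma is (shape, rate)
because the (shape, scale) reading is wildly inconsistent with the
base-case costs.  The printed gamma rate constants are themselves
inconsistent across rows (some only match their base case if read as
units of 10⁻⁴, others are rounded to one significant figure), so the
package keeps the printed shapes — which set the coefficient of
variation — and anchors each rate to shape/base so the mean equals the
base-case cost exactly; a load-time check rejects any beta/gamma whose
mean deviates more than 10% from its base value.

One-way sweeps move a `ParameterGroup` to its low and then high limits
together (common relative position), realizing the positive
correlation of grouped parameters (the nine utilities, the nine
prevalences, the three screening cost components); full joint copulas
are out of scope.  The PSA samples all non-fixed parameters
independently and jointly once per draw, evaluates every strategy on
the common draw, resamples draws that yield an invalid model (counted
and logged), and is deterministic given a seed.  Distributions are not
truncated to the printed ranges (clamping only to semantic domains
such as [0,1]); whether the original analysis truncated is unstated,
and no-truncation is the configurable default.  Acceptability curves
use NMB = λ·QALYs − cost on a willingness-to-pay grid from 0 to 3×
per-capita GDP in 100 steps; in all-competing mode ties split equally
so probabilities sum to one.

## Synthetic natural-history inputs

The transition probabilities, baseline prevalences, detailed cost
expansion and background life table are not published at usable
detail, so `ugicea.synthetic` generates stand-ins:

* **Transition matrix** — onset from normal (EC 0.004/yr, GC
  0.005/yr), stepwise progression (mild→moderate 0.05,
  moderate→severe 0.06, severe→early 0.18, early→advanced 0.35;
  LGIN→HGIN 0.04, HGIN→early 0.15, early→advanced 0.35), regression
  between adjacent precancer states (0.02–0.06), recurrence from
  posttreatment to the corresponding detected state (precancer 0.01,
  early 0.04, advanced 0.08/yr).  Cancer mortality comes from 5-year
  survival via 1 − S^(1/5): overall advanced-stage survival 30.3% (EC)
  and 35.1% (GC) for untreated/advanced states, early-detection
  survival 86% and 90% for early-stage and posttreatment-early states,
  and synthetic treated-advanced survival 40%/45%.
* **Prevalence** — baseline lesion prevalences typical of high-risk
  screening reports (mild dysplasia 5%, moderate 1.5%, severe 0.5%,
  early EC 0.2%, advanced EC 0.05%; LGIN 4%, HGIN 0.4%, early GC
  0.15%, advanced GC 0.05%), all undetected at baseline.
* **Life table** — Gompertz-type annual death probability
  q(a) = 1 − exp(−ℓ·e^{s(a−40)}) with level ℓ = 0.002 (hazard at 40)
  and slope s = 0.09, giving q(40) ≈ 0.002 and q(90) ≈ 0.16, a
  plausible adult mortality schedule.

These values were chosen once as field-plausible defaults and carry
triangular distributions over ±50% ranges (±20% for survival
proportions) so the sensitivity machinery exercises them.  A
`SyntheticConfig` seed jitters them by ±10% to generate distinct
plausible parameter worlds deterministically; scale knobs shift lesion
burden and progression speed wholesale.

**What the synthetic world does and does not show.**  The generator
reproduces the *structure* of the problem — progression chains,
detection tiers, screening economics — so tests passing on it
demonstrate that the machinery (mass conservation, discounting,
event accounting, frontier logic, PSA plumbing) is correct and that
the qualitative conclusions (screening gains QALYs; ICERs far below
the GDP threshold; two-yearly screening optimal; compliance and
utilities the most sensitive inputs) are robust in a plausible world.
It does not calibrate to real incidence or mortality data, so
absolute QALY/cost totals and exact published ICER magnitudes for the
simulated cohort are not reproduced and are deliberately out of
scope; supplying a parameter file with the full published transition,
prevalence and life-table values (same YAML schema,
`ParameterSet.from_yaml`) reproduces the full published analysis.

## Verification

* An independent individual-level microsimulation (tests/oracles.py)
  re-implements the entire process as per-person Bernoulli/categorical
  draws with no shared propagation code; the cohort engine agrees with
  its mean discounted QALYs and costs within 3 Monte-Carlo standard
  errors at 20 000 individuals, for both no screening and two-yearly
  screening.
* Time-homogeneous no-screening dynamics match the matrix-power closed
  form to 1e-9; constant occupancy yields exact person-years
  (half-cycle identity); one-time costs discount at exactly
  (1+r)^−(t+0.5).
* All 52 published ICERs are reproduced from the published incremental
  columns after rounding, and the sequential ladder recomputed from
  the printed totals matches the printed vs-next column in every age
  block.

## Numerical and degenerate-input conventions

Occupancy mass is conserved to 1e-6 of the cohort per cycle; matrices
are validated to 1e-9.  QALY ties in the frontier are compared in cost
order and flagged.  A zero-cycle horizon returns empty accumulations.
Negative occupancy, out-of-range probabilities, missing compliance or
utility entries, and life-table lookups outside support all raise
typed errors; a discount rate outside 0–8% warns.  Problem sizes used
throughout the analyses: 100 000-person cohorts over up to 48 cycles,
100 000 draws for distribution-mean checks, 500 PSA draws per age band
in the analysis driver (reduced counts in the test suite).

## Known limitations

Transition probabilities between precancer states are age-invariant
(real progression rates rise with age, so screening value is likely
overstated at younger ages and understated at older ones); screening
compliance does not decay across rounds; no tunnel states enforce
minimum dwell times; no within-band age heterogeneity; societal-
perspective costs, equity weighting, budget impact and expected value
of perfect information are out of scope.
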