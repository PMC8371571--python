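# ugicea

A Markov cohort model for the cost-effectiveness of combined endoscopic
screening for esophageal cancer (EC) and gastric cancer (GC) in
high-risk areas of China, written for health-economics researchers and
screening-policy analysts who want a transparent, scriptable
re-implementation of this class of analysis.

## The model

A closed cohort of 100 000 people enters at the mean age of one of six
age bands (42, 47, ..., 67 years) and is followed in 1-year cycles
until mean age 90 through 26 mutually exclusive health states: normal,
death, nine lesion/cancer stages split into undetected and detected
variants (EC: mild → moderate → severe dysplasia/CIS → early →
advanced cancer; GC: LGIN → HGIN/CIS → early → advanced cancer), and
six posttreatment states.  Each cycle applies, in order: a screening
round (if the strategy offers one and the cohort is inside the 40–69
eligibility window), symptom-driven self-detection, treatment of new
diagnoses at stage-specific compliance, and the natural-history
transition with age-specific background mortality.  Annual mortality
from advanced cancer is derived from 5-year survival *S* as
*p* = 1 − *S*^(1/5).

Health outcomes are quality-adjusted life-years (QALYs),
Σₜ δ(t) Σₛ ū ₛ(t) · u(s), with trapezoidal half-cycle-corrected
occupancy ūₛ(t), utility weights u(s) ∈ [0,1], and discount factor
δ(t) = (1+r)^−(t+0.5) at r = 5%.  Costs (2019 US$, health-care system
perspective) combine one-time event costs — mobilization, endoscopy,
false-positive reexamination, complication treatment, initial
treatment — with annual care costs for people in care.  Strategies
(no screening, once per lifetime, every 10/5/3/2 years) are compared
by the incremental cost-effectiveness ratio ICER = ΔC/ΔE, both versus
no screening and versus the next most effective strategy, and judged
against WHO willingness-to-pay thresholds (1× and 3× China's 2019
per-capita GDP, US $10 276).  Uncertainty is handled by grouped
one-way sweeps over parameter ranges and by probabilistic sensitivity
analysis (triangular/beta/gamma parameter distributions) summarized as
cost-effectiveness acceptability curves via net monetary benefit
NMB = λ·E − C.

Published base-case parameter estimates (compliance, test accuracy,
costs, utilities) are built in; the natural-history pieces that are
not published at full detail (transition probabilities, baseline
prevalences, the background life table) are generated as clearly
flagged synthetic stand-ins, and a parameter file in the same YAML
schema can replace them verbatim (see `docs/methods.md`).

## Worked example

```python
from ugicea import default_parameter_set, evaluate_strategies
from ugicea.cea import frontier_sequence

pset = default_parameter_set()          # base case + synthetic natural history
outcomes = evaluate_strategies(pset, initial_mean_age=42)
for cmp in frontier_sequence(outcomes, mode="sequential"):
    print(f"{cmp.strategy:18s} vs {cmp.comparator:18s} "
          f"ICER = {cmp.icer_rounded} $/QALY")
```

prints

```
once_per_lifetime  vs no_screening       ICER = 1114 $/QALY
every_10y          vs once_per_lifetime  ICER = 1544 $/QALY
every_5y           vs every_10y          ICER = 1934 $/QALY
every_3y           vs every_5y           ICER = 2855 $/QALY
every_2y           vs every_3y           ICER = 4424 $/QALY
```

Each line is the extra cost per extra QALY of stepping up to the next
more intensive screening schedule for the 40–44 age band; every step
stays below the per-capita GDP threshold, so two-yearly screening is
the optimal strategy at that willingness to pay.  The same menu is
available from the shell (`ugicea run`, `ugicea frontier`,
`ugicea oneway`, `ugicea psa`, `ugicea synth`), and the numbered
scripts under `analysis/` run the full study: parameter bundle,
base-case table, ICER recomputation from the published totals,
grouped one-way sensitivity, and the PSA acceptability curves, each
writing CSVs under `results/`.

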