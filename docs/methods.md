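# Methods

This note documents the model implemented in `osteosim`, its assumptions,
the synthetic inputs, and the numerical conventions, in enough detail to
audit or extend the package.

## Model structure

The disease process is a discrete-time state-transition model for one
postmenopausal woman, advanced in 6-month cycles from the starting age
(default 70) until death or age 100. The seven states are: well; acute
fracture (first year after a hip, vertebral, or "other" fracture — wrist
and other non-vertebral fractures share the "other" box but keep their site
tag for costs and utilities); post-hip; post-vertebral; dead (absorbing).
An acute state lasts exactly two cycles; hip and vertebral fractures then
move to their permanent post-fracture states, wrist/other fractures return
to well. From post-hip only a new hip fracture is possible; from
post-vertebral, a new vertebral or hip fracture; from well and from the
acute states all four sites are at risk (the most permissive reading of the
state diagram; see "Design choices").

### Hazards within one cycle

For a woman alive at cycle start, with age `a`, model month `m`:

* **Death.** Background annual probability `q(a)` from the female life
  table. Post-fracture excess mortality is applied on the hazard scale,
  `q_cycle = 1 − exp(−RR · h · Δt)` with `h = −ln(1 − q(a))` and
  `Δt = 0.5`, because first-year relative risks up to 6.47 would otherwise
  push probabilities past 1 at high ages. The RR is the first-year column
  in acute states, the subsequent-years column in post states (for the
  full time spent there), 1 in well; "other" fractures carry excess
  mortality only in the first (acute) year. Ages outside the printed RR
  bands (70–94) clamp to the nearest band.
* **Fracture.** Per site: annual incidence (age-banded, per-1000) ×
  effective treatment RR × same-site history elevation, capped at 1,
  converted by `1 − (1 − p)^Δt`, and combined across sites as competing
  risks: `p_any = 1 − Π(1 − p_i)`, with the site drawn proportional to the
  per-site hazards. Death is resolved first; survivors sustain at most one
  fracture per cycle.

### Treatment arm

Teriparatide 20 µg daily for 18 months. The per-site relative risks (0.50
hip, 0.35 vertebral, 0.54 wrist, 0.47 other non-vertebral) apply in full
while on treatment. Persistence is 70.3 %/year, evaluated once per cycle at
the start of cycles 1 .. D−1 of a D-cycle course with per-cycle probability
`0.703^0.5`, so exactly 70.3 % of (surviving) starters are on treatment at
12 months. After stopping — by completing the course or by non-persistence
— the effect tapers linearly from the stop month to no effect over 24
months (vertebral) / 30 months (non-vertebral). Drug cost accrues only
while on treatment: one 30-dose-day pen at 4.4 million IRR, i.e.
`round(182.5 / 30 × 4,400,000) = 26,766,667` IRR per 6-month cycle.

### Utilities and costs

Utility per cycle is `u(age) × multiplier × 0.5`, with the first-year
multiplier during the two acute cycles (hip 0.792, vertebral 0.626, wrist
0.977, other 0.87), the subsequent-years multiplier in post states (hip
0.9, vertebral 0.93), and 1 in well. Costs per cycle are: calcium/vitamin
D/naproxen 1.3 m IRR every cycle in both arms; an annual BMD test 1.4 m
booked every second cycle; bed-sore management 4 m per acute hip/vertebral
cycle; and, booked once at the fracture event, the acute management package
(150 m hip, 100 m vertebral, 80 m wrist/other), hip one-offs (wheelchair
10 m, waving bed 10 m), 6 months of home nursing (60 m, hip/vertebral) and
first-year physiotherapy (10.5 m, hip/vertebral). Costs discount at
7.2 %/year, effects at 5 %/year, as `(1+r)^−t` with `t` at cycle start.
Costs and utilities are booked at cycle start for everyone alive at cycle
start, with no half-cycle correction; the trace uses the identical
convention, so the two engines agree exactly in expectation.

## Engines

**Expanded state space.** Duration dependence (acute tunnels, the 5-year
same-site re-fracture elevation in whole years since fracture, first-year
vs. subsequent mortality) is made Markovian by expanding each macro state
with per-site clocks in cycles, capped at 10 (five years). The reachable
combinations are enumerated by breadth-first search (6,852 states with the
default structure; a configurable bound guards against explosion). Clocks
that can no longer influence anything in a state (e.g. a wrist clock in
post-hip) are dropped on entry to keep the space small.

**Microsimulation.** Patients advance in lockstep over the expanded
states with vectorised transitions. Each patient-cycle consumes one block
of four uniforms (persistence, death, fracture, site) drawn only while
alive, which makes `run_microsim(n=1, seed)` bit-identical to
`simulate_individual` with `default_rng(seed)`, and makes common random
numbers across arms available by passing the same seed to both arms
(higher-level drivers default to independent streams per arm, matching the
source analysis's behaviour).

**Cohort trace.** The teriparatide arm is a finite probability mixture
over persistence paths (stop at month 6, 12, …, or complete the course);
conditional on a path the kernel is deterministic in time, and each path's
occupancy vector is pushed forward exactly. The trace is therefore the
exact expectation of the microsimulation — the oracle-equivalence test
(50,000 patients, five seeds, both arms, 3 Monte-Carlo SEs) checks the
sampling engine against it. When every treatment RR is 1 and the drug is
free, the persistence paths are indistinguishable and are collapsed to
one, making the null-treatment identity (ΔC = ΔE = 0) exact to the last
bit rather than to mixture round-off.

## Synthetic inputs (and what they imply)

Two required inputs have no published values; the package generates
transparent stand-ins and accepts user-supplied replacements:

* **Background mortality** — a Gompertz–Makeham life table
  `q(x) = 1 − exp(−(a + b·e^{c·x}))` with a = 0, c = 0.095/year and b
  calibrated by bisection so that remaining life expectancy at age 70 is
  14.0 years (an assumption, chosen as plausible for the modelled
  population, not a measured value). A two-column `age, qx` text file can
  be substituted.
* **Baseline utility** — `u(age) = clamp(0.86 − 0.004·(age − 50), 0.4, 1)`,
  shaped like published EQ-5D female population norms; an explicit
  age→utility table can be substituted.
* The same-site re-fracture elevation is cited but not printed in the
  source; the default schedule [2.0, 1.5, 1.3, 1.2, 1.1] for years 1–5 is
  a **placeholder** and fully configurable.

Because absolute survival and utility levels depend on these stand-ins,
the package's absolute totals (QALYs near 6.8/arm, ICER near 1.0 billion
IRR/QALY under the defaults) are *not* comparable to the published
headline totals, which used unpublished national inputs. What the test
suite does establish: internal consistency (oracle equivalence,
conservation, closed-form reductions), exact recovery of every printed
input, and the qualitative behaviour of the ICER under the published
sweeps (dearer drug → higher ICER; older start age → lower ICER; no
discounting → lower ICER). Passing tests therefore validate the machinery
and directions, not the absolute Iranian cost-effectiveness estimate.

## Sensitivity analysis

* **One-way (tornado).** Default ±25 % around the base case (start age
  swept over its published 60–80 range instead), both arms re-run in trace
  mode, parameters ranked by ICER span. Utility multipliers are capped at
  1; the hip first-year multiplier is excluded from the default sweep list
  because +25 % would exceed its subsequent-years value and violate the
  parameter invariants.
* **Scenarios.** Base case plus the published battery (drug cost ±25 %,
  horizons 5/10 years, all treatment RRs ±25 %, start age 60/80, no
  discounting) and named extras (treatment duration 12/24 months, offset
  none/doubled), all in trace mode with cost-effectiveness labels at 2×
  and 3× GDP/capita (GDP/capita 138 m IRR).
* **PSA.** Distribution bounds are central 95 % intervals: normal for the
  start age (truncated to [55, 90], drawn per iteration); log-normal for
  treatment RRs with the median anchored at the point estimate and
  `sdlog = (ln u − ln l)/3.92`; beta by method of moments for utility
  multipliers; gamma for surgery costs fitted by *exact quantile matching*
  (method-of-moments gamma misses the lower bound by ~4 % at these
  shapes). Surgery draws shift the corresponding acute package by the
  deviation from the catalogue midpoint. The default engine is the cohort
  trace per draw (pure parameter uncertainty); `engine="microsim"` layers
  first-order noise on top and widens the interval estimates accordingly.
  In the rare event a tail draw puts a first-year utility above its
  subsequent-years value, the first-year value is clamped to it. The CEAC
  reports, over a willingness-to-pay grid (default 0–3×GDP in GDP/20
  steps), the fraction of iterations with positive incremental net
  monetary benefit.

## Numerical choices and problem sizes

* Annual→cycle conversion by complement power; RR on the hazard scale
  (both standard; keep probabilities in [0, 1]).
* Band lookups use the integer part of age; incidence above the open-band
  anchor (87) extrapolates linearly through the last two band midpoints
  (82, 87), floored at 0 and capped at 1.
* Life expectancy is the trapezoidal integral of the survival curve
  (deaths credited half a year in their year); Gompertz calibration is
  deterministic bisection on `b` to |LE − target| ≤ 0.05 years.
* Path weights in the trace mixture are normalised to sum to one.
* ICERs are computed on unrounded values; display rounding to integer IRR
  happens only in reports.
* `scripts/acceptance.py` uses 500,000 patients/arm for the base-case
  microsimulation (the incremental QALY is a small difference of two
  independent arms, so smaller cohorts leave the reported ICER dominated
  by Monte-Carlo noise), 100,000 patients for persistence recovery, and
  1,000 PSA iterations in trace mode — sizes chosen so the reported
  quantities are stable at the precision shown.

## Known limitations

* No treatment switching or sequential therapy; no adverse-event states.
* At most one fracture per 6-month cycle.
* Excess post-fracture mortality applies for the whole stay in a post
  state; the true duration of the excess is uncertain.
* The persistence process is independent of health state (a fracture does
  not change the probability of abandoning therapy).
* Currency is integer IRR throughout; the 42,000 IRR/USD rate is metadata
  only — no inflation or conversion machinery.
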