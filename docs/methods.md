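# Methods

## Problem and pipeline

Tunnel transits expose train occupants to gauge-pressure excursions of
hundreds to a few thousand pascals over a few seconds. The package assesses
the resulting aural discomfort in four stages: exterior pressure signature →
interior cabin pressure (seal model) → middle-ear indicator responses →
level classification and duration statistics. Each stage is exposed on its
own; `run_pipeline` chains them over a speed × seal-index × car-position
factorial.

## Seal model

Interior pressure obeys the first-order relaxation

    dP_in/dt = (P_out − P_in) / ω,

with ω the dynamic seal index in seconds (larger = tighter car body;
defaults documented as the service range {4, 8, 12} s, any positive value
accepted). The integrator uses the exact per-sample update for
piecewise-linear input,

    y[n+1] = y[n]·E + u[n]·(1−E) + Δu·(1 − ω(1−E)/h),  E = e^(−h/ω),

which is unconditionally stable and step-size independent; a naive Euler
recurrence exists only in the test suite as an independent oracle (refined
step, 1e−6 relative agreement required). Initial condition P_in(0) = 0: the
cabin is equilibrated at tunnel entry. The same ω applies to all cars of a
train; no per-cabin leakage network is modelled.

A note on the definition of ω: airtightness standards describe ω operationally
as the duration of a natural 4000 → 1000 Pa relief. Under the first-order
model that relief lasts ω·ln 4 ≈ 1.386·ω, not ω; the two definitions differ
by a fixed factor that the source material does not reconcile. This package
treats the differential equation as the canonical definition and exposes the
relief duration as a derived diagnostic, `seal_relief_time(ω, p_start,
p_end) = ω·ln(p_start/p_end)`.

## Middle-ear surrogate

The anatomical finite-element route (CT-reconstructed ossicular chain) is not
reproducible from published information, and at tunnel timescales it is also
unnecessary: loading below 1 Hz against middle-ear natural frequencies of
hundreds of Hz to kHz is quasi-static, so indicator trajectories are governed
by compliances, not modal detail. The package therefore uses a clearly
labelled linear lumped surrogate: two cascaded unit-static-gain second-order
stages (tympanic-membrane stage driven by cabin pressure; ossicle/
annular-ligament stage driven by umbo motion), integrated with an exact
first-order-hold discretisation (`scipy.signal.lsim`). Footplate velocity I3
is a state of the integrator, never a finite difference of I2.

Parameters, defaults and rationale:

| parameter | default | unit | rationale |
|---|---|---|---|
| `umbo_compliance` C | 0.08 | μm/Pa | places interior transients of the study's magnitude (≈200–2500 Pa) across the published threshold bands (T1 = 46.61 μm ↔ ≈580 Pa, T3 = 139.87 μm ↔ ≈1750 Pa), matching the reported pattern of level outcomes |
| `ossicular_ratio` r | 0.41 | — | the published threshold tables themselves fix the footplate/umbo ratio: Tc(I2)/Tc(I1) = 32.97/80.81 ≈ 0.408 |
| stage natural frequencies | 1000 | Hz | any value ≥ 100 Hz gives indistinguishable sub-1 Hz behaviour (enforced lower bound) |
| stage damping ratios | 0.7 | — | conventional near-critical value; irrelevant in the quasi-static band |

The quasi-static closed form (i1 = C·P, i2 = r·C·P, i3 = r·C·dP/dt) is the
package's oracle for the integrator and the fast path for ramp-and-hold
condition loading. Classification uses indicator magnitudes: the published
response curves and thresholds are non-negative, and whether they are signed
or magnitude curves is not stated; signed series remain available.

## Exposure–response thresholds

Binary-coded logistic regressions between levels give the boundary risks
p(x) = 1/(1+e^(α−βx)); the threshold is the 50%-incidence point α/β. T1, T2
and T3 are fit on the two flanking levels' conditions; T4, the critical
comfort/discomfort boundary, pools all conditions ({ideal, good} = 0,
{bad, worse} = 1). T2 and T4 estimate the same physical boundary from
different sample sizes; their mean Tc classifies comfort vs discomfort, and
the level intervals are ideal (0, T1), good [T1, Tc), bad [Tc, T3),
worse [T3, ∞) — lower-closed by convention (ties have measure zero on
continuous responses; the published interval notation is endpoint-ambiguous,
and two published "good" rows start at 0, treated as a typesetting artifact).

Fitting is maximum likelihood via statsmodels' Newton/IRLS solver (maxiter
100, tol 1e−10) with the Wald test on the slope as the reported p-value.
Complete separation is detected (1-D class-order check, convergence check,
slope-sign check) and refused with a diagnostic rather than returning a
divergent fit. Observations are treated as independent Bernoulli trials.

The packaged reference tables carry the published coefficients and
thresholds verbatim. They are internally inconsistent beyond printed
rounding for I1 and I2 (e.g. α/β for I1 T2 gives 79.28 vs the printed 78.87,
I1 T3 gives 135.83 vs 139.87), and marginally so for I3 T1 (5.8464 vs 5.84, a
0.109% deviation — the derived value does not round to the printed cell). The
threshold table is authoritative for classification; the coefficient table is
authoritative for risk curves. One acceptance-style test asserting 0.1%
coefficient/threshold agreement for the I3 row fails on exactly that printed
T1 cell and is left failing as documentation of the source-data defect.

## Synthetic data

**Exterior traces.** No functional form of the measured traces is published;
the generator uses a piecewise-smooth template — a positive lobe over the
first 18% of the transit, a smoothstep negative ramp to a plateau at 85–92%,
then partial (12%) recovery — with the positive-lobe weight falling from
0.32 (MP-1) to 0.015 (MP-5). Scaling choices: peak-to-peak amplitude ∝ speed²
(standard aerodynamic pressure scaling; the source only shows growth with
speed) and per-point factors 1.00/1.36/1.50/1.56/1.60 following the published
interior pressure-difference ratios at 250 km/h, made strictly increasing at
the tail where the published cells tie within scatter. The base amplitude
(1530 Pa exterior peak-to-peak at 250 km/h, MP-1) is calibrated once so the
ω = 4 s interior pressure difference at that cell reproduces the published
572 Pa; the published 572/318/220 Pa seal progression then emerges from the
filter itself (this package: 572/332/233 Pa). Three seeded low-frequency
sinusoidal components at 0.5% of peak-to-peak each, windowed to vanish at the
endpoints, make traces realisation-dependent without threatening the ordering
invariants. Sampling step 1 ms, mirroring the 1 kHz sensor rate of the
moving-model tests.

**Condition design.** The 116 quasi-static conditions (19/20/38/39 per
level) are uniform draws from per-level (amplitude, rate) strata inside the
3 kPa / 0.5 kPa/s envelope. The exact published values are unreleased; the
strata overlap by design so boundary fits are non-degenerate, with amplitude
overlap midpoints at 580/1010/1750 Pa — the published I1 thresholds divided
by the default umbo compliance — so refitting the chain end-to-end recovers
I1 boundaries near the published row. Rates are capped by the envelope;
consequently the published I3 bad/worse boundary (20.45 μm/s, which would
require ≈620 Pa/s quasi-statically at the default calibration) is not
reachable within the stated envelope, and recovery tests assert the design's
own generating boundaries, not the published I3 row.

**What passing tests do and do not show.** The synthetic family reproduces
the *structure* of the measured data — trace morphology, amplitude orderings
across speed/seal/position, and the direction of every reported duration
effect — not its numerics. Measured traces contain reflected-wave
oscillations, inter-run variability and sensor noise that the template
omits, so the reported headline percentages (e.g. the tinnitus-band duration
falling from 31.9% to 3% between ω = 4 and 12 s) are reproduced in character
(this package: 39.4% → 5.5% on the default factorial), not asserted
numerically.

## Classification and aggregation

Each indicator sample is classified by magnitude into exactly one level;
duration summaries are sample-count percentages over the transit window
(head-car entry to tail-car exit). Control-variable aggregation pools the
full factorial of the two non-target factors, weighting by actual transit
time (percent × duration), since transits at different speeds last different
times; whether the source pooled seal indexes time-weighted or equally is
unstated — time-weighting is the documented choice here. Per-indicator label
streams are kept separate; no fusion into a single verdict is attempted.
Percentages are renormalised after pooling so the sum-to-100 invariant holds
to 1e−6.

## Problem sizes and numerics

Default factorial: 3 speeds × 3 seal indexes × 5 points = 45 transits of
4.4–6.2 s at 1 kHz (≈200k interior samples per run); threshold refits use
the 116-condition design through the quasi-static path; the parameter-recovery
study uses 100 replicates of n = 500. The pipeline is deterministic given the
configuration seed: trace noise streams are keyed by (seed, point, speed,
scale), design draws by (seed, design size), so results are independent of
evaluation order. Degenerate inputs are rejected at construction (non-uniform
grids, non-positive ω, empty label streams, unbalanced factorials, single-class
or separated logistic inputs).

## Known limitations

- The middle-ear surrogate is linear; kPa-scale static loads stiffen the real
  tympanic membrane and annular ligament, so indicator magnitudes at the top
  of the worse band are upper bounds.
- No acoustic-frequency content: the assessment covers the slow pressure
  transient only, not tunnel noise, so total discomfort is underestimated
  where noise is significant.
- The seal model is a single lumped time constant; door/HVAC leakage
  networks, pressure-tightness degradation with service age and train
  intersections in tunnels are out of scope.
- Synthetic traces are templates, not aerodynamics: no method-of-
  characteristics wave tracking, no portal/hood effects.
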