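# Methods

## The simulator

`popchaos.population` implements a daily-step individual-based model of a
*Daphnia*-like population in one litre of medium. Each individual carries
an age (days), a body length (mm), a brood timer, a starvation counter and
a fixed maximum lifetime drawn once at birth from a uniform integer range.
The daily update applies, in this fixed order: food replenishment,
ingestion, growth, reproduction, survival, ageing. The census (neonates
< 1.4 mm, juveniles 1.4–2.6 mm, adults ≥ 2.6 mm, total) is taken after the
update; day 0 is the founding census of 5 neonates and 3 adults.

Competition acts through a shared food pool. An individual's maximal daily
ration is `ingestion_coeff · L²`; realized intake scales with a saturating
function of food density, `F/(F + half_saturation)`, and is further scaled
down when total demand exceeds the pool. The realized ration fraction
drives everything downstream: the von Bertalanffy length increment
`growth_rate · (L∞ − L) · ration`, the brood size, and starvation (a day
with ration below `starvation_ration` increments a counter, a fed day
decrements it; death at `starvation_days`). Adults whose brood timer has
reached `brood_interval` release `round(max_brood_size · ration ·
(1 − inhibition))` neonates and restart the timer, empty broods included.

Survival removes an individual whose age has reached its maximum lifetime
at the start of the survival stage (it lives `max_lifetime` full days) or
whose starvation counter hits the tolerance. The toxicant acts through the
log-logistic reproduction inhibition `c^h / (c^h + EC50^h)`; an acute
mortality term anchored at the 48-h LC50 (0.23 mg/l) is available behind
`DoseResponse(acute_mortality=True)` but is off by default because the
tested panel lies far below acute lethality.

The only randomness is the lifetime draw; everything else is deterministic
given the state. Two consequences shape the whole design: a run is
bit-identical under its seed, and run *i* uses seed `base_seed + i` at
*every* concentration, so treatments are paired run-by-run.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| length_at_birth | 0.8 | mm | neonate size at release |
| asymptotic_length | 4.0 | mm | large adult *D. magna* |
| growth_rate | 0.10 | 1/day | maturity (2.6 mm) ≈ 13 days at full ration |
| brood_interval | 3 | days | inter-moult brood cycle |
| max_brood_size | 12 | offspring | well-fed brood size |
| lifetime_range | 30–60 | days | randomized fixed maximum lifetime |
| food_input | 20 | mg C/day | supports populations of order 10²–10³ |
| food_cap | 40 | mg C | algal standing stock saturates |
| ingestion_coeff | 0.05 | mg C/mm²/day | adult (3 mm) eats ≈ 0.45 mg C/day |
| half_saturation | 3.0 | mg C/l | ingestion functional response |
| starvation_ration / days | 0.1 / 6 | – / days | famine tolerance |
| ec50_repro | 21.5 | µg/l | reproduction-inhibition EC50 |
| hill_slope | 0.82 | – | shallow chronic dose–response |

The life-history and dose–response defaults were fixed by a grid-search
calibration with two goals: (i) the control ensemble is non-extinct,
bounded, and chaotic with mean Kantz λ in [0.3, 0.7] per day; (ii) along
the default panel {0, 2.5, 5, 10, 20, 40} µg/l the effective fecundity
`max_brood_size · (1 − inhibition)` moves through monotonically declining
parts of the simulator's λ response while avoiding a narrow fecundity band
(effective brood ≈ 5) where synchronized starvation crashes can extinguish
the population. With these defaults the dynamics are driven by
boom-and-crash cycles of the capped food pool; the randomized lifetimes
desynchronise the cohorts enough that runs diverge and the ensemble carries
genuine distributional information.

The optional parameters `starvation_length_scale` (length-graded famine
tolerance), `starvation_jitter` (individual tolerance offsets derived from
the lifetime trait) and `crowding_scale` (Ricker-type brood suppression)
are alternative regulation structures retained for experimentation; all
default to off because each of them damps the crash-driven chaos that the
default calibration relies on.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis needs: daily
age-class-resolved counts over 365 days, bounded chaotic control dynamics,
reproduction-mediated chaos suppression under stress, seed-paired
Monte-Carlo ensembles. It does not emulate a calibrated laboratory
population: no toxicokinetics, no egg-development stage or abortion
endpoint, no temperature or photoperiod forcing, no demographic noise
beyond the lifetime draw. Passing tests therefore demonstrate that the
*method* (embedding → λ → paired inference → threshold) behaves as claimed
on data with this structure, not that a real culture has a particular λ.

## Nonlinear analysis layer

**Transient.** The first 50 days of every series are discarded; analyses
run on the remaining 316 samples of a 365-day run.

**Embedding.** Scalar analyses use delay embedding with m = 2, d = 1;
Poincaré sections use m = 3. `scan_embedding` reports ACF-based delay
heuristics (first zero crossing, 1/e decay) and Kennel
false-nearest-neighbour fractions for candidate (m, d), but it is advisory:
the pipeline's published defaults are fixed for reproducibility rather than
re-optimised per series. The ACF uses the biased 1/N normalisation, which
guarantees |r(k)| ≤ 1.

**Recurrence and sections.** Recurrence matrices use the Euclidean norm by
default (maximum norm available) with the threshold either absolute
(ε = 1 abundance unit, the classical choice for integer counts) or a
quantile of the pairwise distances — the quantile mode exists because an
absolute ε is scale-sensitive across treatments whose abundances differ.
The determinism fraction is standard RQA DET (share of off-diagonal
recurrence points on diagonals of length ≥ 2, main diagonal excluded);
note that an n×n all-recurrent matrix scores (n²−n−2)/(n²−n), not exactly
1, because the two corner diagonals have length 1. Poincaré sections cut
the trajectory at the median of the chosen coordinate (transversal by
construction), single orientation ("up") to count one crossing per cycle,
with linear interpolation in time between the bracketing samples.

**Lyapunov estimation.** `kantz_stretching` follows the Kantz projection
form: neighbourhoods are found on the full delay vectors (KD-tree), future
distances are the scalar |x(i+Δn) − x(j+Δn)| measured from the last
embedding coordinate. Numerical choices:

- Theiler window defaults to (m−1)d + 1; temporally adjacent points would
  otherwise inflate neighbourhoods and bias λ towards zero.
- Reference points need ≥ `nf_min` = 10 neighbours, suppressing
  fluctuation-dominated references.
- Integer-valued series produce exact ties; zero distances are floored at
  half the minimal nonzero gap between observed values so S stays finite
  without discarding ties.
- The default ε schedule is 4 log-spaced radii between the 1st and 10th
  percentile of the embedded pairwise distances (computed on an evenly
  thinned subsample for O(1) cost), floored at the data resolution — a
  radius below the minimal value gap captures only exact repeats.
- The scaling region is chosen automatically: candidate windows are
  anchored at Δn ∈ {1, 2, 3} (windows drifting into the saturation plateau
  report spuriously small slopes; the initial "shoulder" of the projection
  distance can fake divergence on periodic signals) and accepted when
  tightly linear, R² ≥ 0.98 over ≥ 4 points, with a relaxed R² ≥ 0.9 pass
  anchored at Δn ≥ 2 for the shallow divergence of strongly autocorrelated
  series. If nothing qualifies, the best 3-point window is reported with a
  `no_scaling_region` flag.
- The headline λ is the median slope across the ε schedule; per-ε fits and
  curves are kept in the results object. λ is reported per time step
  (per day for the simulator).

The estimator was validated against an independent tangent-space oracle
(Benettin renormalisation with the exact Jacobian) on the logistic and
Hénon maps: agreement within 0.07 across periodic and chaotic regimes, and
within 10% of the analytic ln 2 for the fully chaotic logistic map. A
noise-free stable cycle with strongly negative λ is not recoverable by any
neighbour-divergence estimator (its stretching curve is flat, slope ≈ 0),
so the oracle-equivalence check uses periodic parameters near bifurcation
points where |λ| is small; deeply contracting regimes are asserted to be
*not called chaotic* rather than matched numerically.

## Ensemble inference

One λ per (concentration, age class, run) forms the Lyapunov table; cell
summaries use the arithmetic mean and sample standard deviation (n−1).
Estimates carrying the `no_scaling_region` flag are treated as invalid and
excluded pairwise, with the effective n reported per comparison. All
unordered concentration pairs are tested with the Wilcoxon signed-rank
test, paired by run index (shared seeds make this pairing exact); the
implementation enumerates the exact null for n ≤ 25 without ties and
otherwise uses the normal approximation with tie and continuity
corrections, dropping zero differences. p-values are reported raw by
default — a Holm step-down adjustment is available behind a flag — and an
unpaired rank-sum fallback exists for data without aligned runs. The
disturbance threshold is the lowest non-control concentration with
p(control, c) < α (α = 0.05); "none" is a legal outcome.

λ > 0 is used as the chaos criterion downstream (with boundedness checked
at the simulator level). The threshold detector is monotone in α by
construction: lowering α can only raise the threshold.

## Pipeline sizes and determinism

The shipped experiment sizes are scaled for a single CPU: the test suite
exercises ensembles of 20 runs × 6 concentrations × 4 series types
(365-day runs), and the acceptance script uses 50 runs per concentration;
both complete in tens of seconds. The full pipeline is deterministic under
its base seed: per-run seeds are `base_seed + run index`, concentration
never enters the seed, and repeated runs produce byte-identical artifacts.

## Known limitations

- The simulator is a minimal mechanistic stand-in, not a calibrated
  laboratory model; its λ values characterise the method, not *D. magna*.
- λ estimates on 316-point integer series carry noticeable per-run
  variance; distributional statements (the point of the method) are
  robust, single-run values should be read with their fit diagnostics.
- The dose–response is a single log-logistic acting on brood size; mixed
  or time-varying exposure, toxicokinetics and acute mortality at high
  doses are out of scope (the acute term exists but defaults to off).
- The automatic scaling-region search is tuned for series of a few hundred
  to a few thousand samples with t_max ≈ 12; very short or very long
  horizons may need an explicit `fit_range`.
- Recurrence/Poincaré outputs are descriptive companions to λ; the
  package does not attempt full recurrence quantification (laminarity,
  trapping time) or attractor-stability landscapes.
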