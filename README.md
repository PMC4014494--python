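# popchaos

Chaos detection and disturbance-threshold inference for age-structured
population dynamics under chemical press disturbance.

## The problem

Sustained ("press") chemical stress can alter the *dynamics* of a
population long before it changes obvious endpoints such as mean abundance.
A daphnid population regulated by food competition and crowding typically
fluctuates chaotically: nearby population states diverge exponentially at a
rate measured by the maximal Lyapunov exponent λ. Sub-lethal reproduction
inhibition damps this chaotic component — the population becomes more
periodic, more predictable, and (by the chaos-mediated-survival argument)
less resilient. `popchaos` operationalises that idea as a statistical test:
simulate a Monte-Carlo ensemble of an individual-based *Daphnia*-like
population across a panel of constant toxicant concentrations, estimate λ
for every run, and find the lowest concentration whose λ distribution
separates significantly from control. The package is aimed at stress
ecologists and ecotoxicological modellers who want a dynamics-based
no-effect threshold from population time series — simulated or observed.

## What it computes

For a scalar abundance series x(n) (daily counts, transient removed) the
phase space is reconstructed by time-delay embedding,
y(n) = [x(n), x(n+d), …, x(n+(m−1)d)], by default with m = 2, d = 1.
The maximal Lyapunov exponent is estimated with the Kantz
stretching-curve method: for every reference point y(i) with at least
`nf_min` = 10 neighbours inside a radius ε (temporal neighbours excluded by
a Theiler window),

    S(Δn) = ⟨ ln( mean_{j ∈ U(i)} |x(i+Δn) − x(j+Δn)| ) ⟩_i ,

and λ is the least-squares slope of S over its linear scaling region
(units: 1/day). λ > 0 on a bounded attractor indicates chaos. Recurrence
plots (with the standard RQA determinism fraction) and Poincaré sections
characterise the attractor geometry. Ensemble inference uses the paired
Wilcoxon signed-rank test — runs share seeds across concentrations, so run
i is its own control — and the disturbance threshold is the lowest tested
concentration with p < α against control.

The simulator is an individual-based model with the drivers that matter for
this question: a shared, capped food pool (ingestion ∝ body length²,
saturating in food density), von Bertalanffy growth scaled by realized
ration, brood size scaled by ration and by a log-logistic
concentration–response (EC50 = 21.5 µg/l, Hill slope 0.82 for a
3,4-dichloroaniline-like compound whose dominant sub-lethal effect is
reproduction inhibition), starvation mortality, and a fixed maximum
lifetime drawn once per individual — the only stochastic element, so runs
are bit-reproducible given a seed.

## Worked example

Estimate λ for a series with a known exponent (the fully chaotic logistic
map, λ = ln 2 ≈ 0.693):

```python
from popchaos import KantzLyapunov, logistic_map

res = KantzLyapunov(logistic_map(4.0).orbit(5000)).fit()
print(res.summary())
```

```
Kantz maximal Lyapunov exponent
============================================
lambda (1/step)    0.6626
fit range (dn)    1..6
fit R^2            0.9923
eps schedule      0.00917, 0.0214, 0.0498, 0.116
flags             none
```

The estimate (0.663/step) is the median slope across four neighbourhood
radii; the fitted scaling region Δn = 1..6 is tightly linear (R² = 0.99).

Run a scaled-down version of the full experiment (20 runs per
concentration, 365 days each) and locate the threshold:

```python
from popchaos import ExperimentConfig, run_experiment

bundle = run_experiment(ExperimentConfig(n_runs=20, base_seed=0))
print(bundle.results.summary())
```

```
 concentration age_class     mean       sd  n
           0.0     total 0.527050 0.120890 20
           2.5     total 0.380569 0.041954 20
           5.0     total 0.363964 0.020249 20
          10.0     total 0.357886 0.028253 20
          20.0     total 0.212247 0.045411 20
          40.0     total 0.186918 0.025959 20
------------------------------------------------------------
threshold [total    ] (alpha=0.05): 2.5 µg/l
```

(Age-class rows omitted here for brevity.) Every run at every treatment has
λ > 0 — bounded chaotic dynamics throughout — while the mean λ of the
overall population declines monotonically with concentration, from 0.53 in
control to 0.19 at 40 µg/l: the stressor progressively suppresses the
chaotic component. The paired signed-rank test already separates the lowest
tested dose from control, so the detected disturbance threshold is
2.5 µg/l.

The same pipeline runs from the shell:

```bash
popchaos run-all --out results/ --seed 0 --runs 20
popchaos simulate --out data/ --seed 0        # CSV ensembles only
popchaos analyze --data data/ --out results/  # analyse external CSVs
popchaos threshold --results results/
```

External data are accepted as `conc_<value>/run_<i>.csv` trees with the
header `day,neonates,juveniles,adults,total`.

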