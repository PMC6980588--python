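# otolife

Otolith-based life-history analysis for long-lived, data-poor reef fishes:
bomb-radiocarbon validation of age estimates, between-reader ageing
precision, habitat-depth inference from seawater DIC Δ¹⁴C, and Bayesian
estimation of growth, gear selectivity and mortality from fishery
length-age data. The motivating application is Warsaw grouper
(*Hyporthodus nigritus*) in the northern Gulf of Mexico — a deepwater,
protogynous grouper with validated longevity above 60 y — but every stage
is generic.

## What it computes

**Bomb-radiocarbon chronometer.** Atmospheric nuclear testing in the
1950s–60s drove a rapid, dated rise in marine Δ¹⁴C. An otolith core records
the Δ¹⁴C of the water in the fish's first months; plotting core values at
the estimated birth year (collection year − opaque-zone count) against a
coral/known-age-otolith reference curve validates the ageing. The reference
curve is fit by loess (degree 2, span 0.20) with Bonferroni-corrected
confidence bands; consistency is tested on the residuals (Shapiro–Wilk and
Levene pre-checks, one-sample mean-zero test at α = 0.05), and ageing bias
is profiled as the sum of squared residuals SSR(s) under purposeful age
shifts s ∈ {−3…+3} y — unbiased ages minimise SSR at s = 0.

**Ageing precision.** Beamish–Fournier average percent error
APE = mean over fish of (100/R) Σᵢ |xᵢⱼ − x̄ⱼ| / x̄ⱼ, Chang's mean CV
(sample-SD form; CV = √2·APE for two readers), and percent agreement
within ±t years.

**DIC depth regression.** OLS of seawater DIC Δ¹⁴C on depth inside the
outer-shelf window (200–600 m), reported as ‰ per metre and ‰ per 100 m.
Core Δ¹⁴C matching surface (<200 m) DIC values places juveniles in mixed-
layer shelf waters.

**Growth and mortality.** Naive least-squares von Bertalanffy fits fail on
fishery data because gear selection and size-selective mortality distort
length-at-age. The package instead builds a stable catch composition
P(age, length-bin) from: VBGF mean length μₐ = L∞(1 − e^(−k(a−t₀))),
G = 21 persistent growth-type groups spanning a length CV, logistic
selectivity V(l) = 1/(1 + e^(−(l−l₅₀)/γ)), and cumulative survival
exp(−(M + F·V)). Observed (age, length) pairs are multinomial draws from
this grid; the eight parameters (L∞, k, t₀, CV, l₅₀, γ, M, F) get
log-normal priors — informative on M, from the Hewitt–Hoenig longevity
estimator M = 4.22/t_max — and are sampled by multi-chain random-walk
Metropolis–Hastings on the log scale, with Gelman–Rubin, Geweke and
Heidelberger–Welch diagnostics. Derived outputs: Z = F + M and the
overfishing indicator F:M.

Synthetic-data generators (bomb curve, DIC profile, double age reads,
fished population) reproduce the statistical structure each stage assumes,
so the whole pipeline runs and is testable with no external data. The 14
published otolith-core Δ¹⁴C measurements ship with the package.

## Worked example

```bash
python examples/dic_depth_profile.py
```

```
points in 200-600 m : 12
slope               : -0.286 permil/m  (-29 permil per 100 m)
R^2                 : 0.96
p-value (slope)     : 1.49e-08
```

The regression uses only bottles tripped between 200 and 600 m; Δ¹⁴C
declines by ~29 ‰ per 100 m of depth below the mixed layer, so
bomb-enriched core values can only have formed in shelf waters.

```bash
python examples/growth_mortality_fit.py
```

```
simulated catch: n=1338, ages 3-29, lengths 217-1866 mm
parameter           truth  post.mean  log-SD
linf             1533.000   1542.673   0.031
k                   0.140      0.122   0.056
t0                  1.820      0.299   0.420
cv_len              0.170      0.176   0.019
l50               812.000    812.508   0.016
sel_steepness      78.800     68.474   0.073
m_nat               0.066      0.056   0.095
f_mort              0.340      0.297   0.067

Hewitt-Hoenig M from t_max=29: 0.146 /y
Z = F + M = 0.354 /y ; F:M = 5.2:1  (F:M > 1 indicates overfishing)
naive least-squares VBGF for comparison: Linf=1279, k=0.179, t0=0.88  (biased by gear selection)
```

The sampler recovers L∞, the selectivity curve and F from gear-selected
data while the naive least-squares fit is displaced; M barely updates from
its informative prior (its posterior log-SD stays near the prior's 0.1),
showing that only total mortality is estimable from composition data.
Other examples cover reader precision, bomb-radiocarbon validation and the
full orchestrated pipeline (`otolife run` on the command line).

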