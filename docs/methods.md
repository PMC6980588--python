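# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and what the tests do and do not establish.

## Bomb-radiocarbon reference curve and validation

**Loess dialect.** The reference Δ¹⁴C series is smoothed with classic
Cleveland loess: at each query point the span fraction (default 0.20) of
nearest data points is tricube-weighted (bandwidth = distance to the k-th
nearest point) and a degree-2 polynomial is fit by weighted least squares.
No robustness iterations. Loess variants differ enough between software
environments that this matters: span here is a fraction of points, and the
point at the bandwidth gets weight zero. Predictions are refused outside
the fitted year range (extrapolating a bomb curve is meaningless).

**Confidence bands.** Each prediction is a linear functional l(x)ᵀy, so
SE(x) = s·‖l(x)‖ with s² = RSS/(n − tr L) and L the smoother matrix at the
data points; intervals are Student-t on n − tr L degrees of freedom, with
the per-comparison level α/m for a Bonferroni family of m points
(default: the number of core samples compared). Caveat: Bonferroni
guarantees simultaneous coverage only for an unbiased estimator. Degree-2
loess is exactly unbiased on locally quadratic means (where simulated
coverage of the 14-point band exceeds 95%), but near the sharp 1974 bomb
peak smoothing bias consumes the Bonferroni slack and realised coverage is
approximately nominal (94–95%) rather than conservative. The test suite
checks the conservative claim on a quadratic mean and a 90% floor on the
bomb curve.

**Birth years.** Year of formation = calendar collection year − integer
age; months are ignored. The shipped published core table contains three
rows whose printed year of formation contradicts this rule; they are
flagged, never corrected, because nothing identifies which field is the
typo.

**Residual test.** Residuals are core Δ¹⁴C minus the loess prediction at
the birth year. Samples whose birth year precedes the fitted range are
excluded and reported (a pre-rise birth year cannot be validated by the
chronometer). Pre-checks: Shapiro–Wilk normality and Levene variance
homogeneity between early/late birth years split at the median. The
consistency call is a one-sample t test of mean zero at α = 0.05 — the
test statistic behind the published "no significant difference" is not
named, and a mean-zero t test is the reading adopted here. Calibration at
the study scale (14 cores, 6 ‰ noise) holds the 5% size within 2 points
over 1,000 replicates and exceeds 80% power against a +3 y age bias on the
rise; calibration simulations use 500-point reference series so that
reference-curve error is negligible against core noise.

**SSR age-shift profile.** Shifts are age shifts: +s years of ageing bias
moves every birth year s years earlier, so SSR(s) = Σ(Δ¹⁴Cᵢ −
fit(yᵢ − s))². Two residual definitions are computed: on the Δ¹⁴C axis
(primary, the bias-plot convention) and on the year axis via inverse
prediction of the fitted curve restricted to its monotone rise segment.
Inverse prediction of values below the pre-bomb plateau (or above the
peak) clamps to the segment boundary and flags the sample. Shifted birth
years outside the fitted range are clipped and flagged. The published SSR
values cannot be recomputed without the undeposited coral/red-snapper
reference series; the testable property is that on-curve samples minimise
SSR at shift 0 (≥95% of replicates under 6 ‰ noise on the rise, where the
curve climbs ~13 ‰/y).

## Synthetic-data generators

All generators take explicit integer seeds (numpy Generator; no global
state) and equal their closed-form means exactly at zero noise.

**Bomb curve.** Monotone piecewise-cubic (PCHIP) mean through four
anchors: a flat pre-bomb plateau (−55 ‰) up to the 1959 rise start, a peak
of +140 ‰ at 1974, and +45 ‰ at 2015, clamped outside; i.i.d. Gaussian
noise (default 6 ‰). Anchor levels follow measured regional values
(−60.7 ‰ for a 1958 cohort, +139.1 ‰ at 1975, +52.7 ‰ at 2008). The
default 120 points span 1949–2015 labelled coral (≤2004) / otolith
(>2004). What it does not emulate: the real regional rise is faster than
the smooth interpolant (measured 1966 cohorts already exceed +120 ‰),
inter-site spread, and measurement-error heterogeneity. Consequently the
published cores overlaid on the synthetic curve do not reproduce the
published SSR profile — by design the synthetic curve is a stand-in for
method testing, not a reconstruction of the regional record.

**DIC profile.** Mean = surface level (+60 ‰) down to the mixed-layer
depth (200 m), then linear decline at −0.289 ‰/m (the measured slope used
as generator truth) to 1,248 m; Gaussian noise, default 5 ‰ chosen to
reproduce the reported fit quality (R² ≈ 0.97 over the 200–600 m window).
Default 40 bottles across three stations on an even grid from 5 m.

**Reader error.** Gaussian on the age scale with SD = 0.08 × true age
per read, rounded to integers and floored at 1 y; an optional systematic
bias applies to the second reader. The true error process was never
measured; this stand-in was chosen to give between-reader statistics of
the right order (APE ~5%, ±1 y agreement ~80% on a realistic age
distribution) while remaining a single-parameter model. Note the model is
proportional-error only: it under-produces the disagreement observed for
real thin sections at young ages, so simulated exact-agreement rates run
lower and APE somewhat lower than published values.

**Fished population.** Multinomial draws from the catch-composition grid
(below), with length uniform within the drawn 50-mm bin. At the published
posterior values the composition places ~56% of the catch below age 10,
not the ~94% of the observed fishery data — the observed age structure
also reflects recruitment and sampling processes outside the stable-
composition model, so tests assert right-skew, not the published
percentage.

## Catch composition and likelihood

Ages 1…65; 50-mm length bins spanning 0–2,500 mm; G = 21 equal-probability
growth-type groups with persistent relative deviations
δ_g = Φ⁻¹((g−0.5)/G)·CV; group length l_ga = μₐ(1+δ_g) floored at 1 mm
(the floor also handles ages below t₀); survivorship S_g,1 = 1,
S_g,a+1 = S_g,a·exp(−(M + F·V(l_ga))); cell mass w_g·S_ga·V(l_ga)
accumulates into the bin containing l_ga; ε = 1e−10 is added to every cell
before normalisation so the multinomial log-likelihood is finite
everywhere. G, bin width, age cap, floor and ε are configurable
(`GridSpec`). Two exact consequences used as tests: with V ≡ 1 the age
marginal is geometric in total mortality, and with F = 0, V ≡ 1 the
composition's mean length-at-age equals the VBGF mean to within bin
discretisation (<0.5% for ages ≥ 5; younger ages sit in the first bins
where the 1-mm floor and 25-mm half-bin dominate tiny μₐ). Faster-growing
groups are thinned harder under F > 0, so fished mean length at old ages
drops below the unfished mean — the mechanism that defeats naive VBGF
fitting.

The likelihood kernel is numba-jitted when numba is importable, with an
equivalent pure-numpy path (~70 µs/evaluation either way at default grid
size; the jitted path matters for full-length chains).

## Priors and MCMC

All eight parameters are sampled as x = ln θ with independent normal
priors on x (natural-scale median, log-space SD). Defaults: weak priors on
growth (L∞ median 1,618 mm, log-SD 5; k 0.13, log-SD 2; t₀ 0.2, log-SD 2),
length CV (0.12, log-SD 2), selectivity (l₅₀ 880 mm, log-SD 5; spread γ
5 mm, log-SD 2), F (0.2, log-SD 2), and an informative prior on M centred
on the Hewitt–Hoenig longevity estimate (0.069 y⁻¹, log-SD 0.1). The
"steepness" of selectivity is implemented as the logistic spread γ in mm —
consistent with a weak prior of 5 updating to ~79 — because no units were
published. Log-scale sampling structurally enforces t₀ > 0.

Sampling is random-walk Metropolis–Hastings with burn-in-only adaptation
in two phases: componentwise updates with per-parameter scale tuning
toward 20–40% acceptance (robust mode finding), then joint proposals with
covariance estimated from the accumulated burn-in draws (2.38²/d scaling,
scalar multiplier nudged into the same acceptance band). After burn-in the
proposal is frozen, so the sampling phase is a standard time-homogeneous
Metropolis chain. Chain c uses seed = master seed + c; initial points are
the prior medians with a small (0.05 log-unit) chain-specific jitter so
multi-chain diagnostics are not trivially passed. Defaults follow the
production setting (4 chains, 5,000 burn-in, 200,000 samples); tests and
examples reduce lengths.

**Known mixing limit.** The posterior is a curved ridge in (L∞, k, t₀):
compositions with lower t₀ and lower k are nearly indistinguishable from
the truth given gear-selected data, and t₀ itself is weakly identified (the
catch contains almost no fish young enough to pin it). At 4 × 20,000 draws
the Gelman–Rubin PSRF on ridge parameters routinely exceeds 1.1 even
though point recovery of L∞ (±5%), k (±20%) and F (±30%) is stable across
chains and prior settings; full-length runs mix proportionally better.
Reported posterior means are E[θ] over pooled post-burn-in draws
(natural scale); reported SDs are SDs of the log-scale draws.

**Diagnostics.** Classic Gelman–Rubin PSRF (√(((n−1)/n·W + B/n)/W));
Geweke z comparing the first 10% and last 50% of each chain with
batch-means standard errors; and a Heidelberger–Welch-style Cramér–von
Mises stationarity test on the standardised cumulative sum (critical value
0.461 at α = 0.05). Overall pass requires PSRF < 1.1, |z| < 2, and every
chain stationary.

**Non-estimability of M.** Because the data inform only total mortality,
the posterior for M reproduces its informative prior (log-SD within ~10%
of the prior's 0.1 in recovery runs); F is therefore conditioned on the
M prior, and F:M should be read accordingly.

## Mortality bookkeeping

Hewitt–Hoenig longevity estimator M = 4.22/t_max, rounded to 3 decimals
for reporting (61 y → 0.069 y⁻¹). Z = F + M exactly. The F:M ratio is
returned exactly and, for reporting, truncated (not rounded) to one
decimal — the convention under which the printed posteriors F = 0.34,
M = 0.066 yield the published 5.1:1 (plain rounding of 5.1515 would give
5.2).

## Naive least-squares VBGF

Unconstrained `curve_fit` of L∞(1−e^(−k(a−t₀))); non-convergence is
reported, not raised. On gear-selected catch data the fit is biologically
misleading: simulations at the study truth show t₀ biased well below its
true value with L∞/k displaced. The very large negative t₀ of the
published real-data fit additionally reflects fishery-independent small
juveniles mixed with gear-selected adults, a mixture the pure catch-
composition generator cannot produce; the tests therefore assert the
direction and magnitude of the bias, not the published point values.

## Pipeline

Stages (inputs → precision → radiocarbon → DIC → growth) are pure
functions of the configuration and master seed: sub-seeds are fixed
offsets of the master seed, report.json contains no timestamps or
versions (those go to run.log), so identical config + seed reproduce the
report byte-for-byte. Missing inputs skip a stage with a logged notice;
stage failures keep partial outputs and exit nonzero. Dates are normalised
to ISO 8601 on input (MM/DD/YYYY accepted); "NM", "--" and empty cells are
missing, never zero.

## Test problem sizes

Simulation-based tests use: 200 replicates for the SSR-minimum check;
1,000 (size) / 200 (power) replicates for residual-test calibration; 500
replicates for band coverage; n = 100,000 draws for the composition
goodness-of-fit; n = 200,000 for mean-length-at-age sampling checks (the
per-age Monte-Carlo error at 50,000 would be commensurate with the 1%
tolerance being verified); and 4 × 20,000 post-burn-in draws for the
growth-recovery checks with n = 1,338 observations. Prior-recovery uses
6 × 200,000 draws because the 5%-of-median check on a log-SD-5 prior needs
roughly 10⁴ effective draws.

## Limitations

No sex-specific growth (no sex data), no time-varying F or recruitment, no
radiocarbon decay/fractionation corrections (performed upstream at the
AMS facility), no spatial sampling structure, and no stock-assessment
reference points. Passing tests establish that the estimators are correct
under the generators' assumptions; they cannot establish that real otolith
reading errors, the real regional Δ¹⁴C history, or the real fishery's
selection process match those assumptions.
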