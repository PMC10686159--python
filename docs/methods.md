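# Methods

## Model and assumptions

The package treats a panel of regional annual rate series as a single
multidegree-of-freedom (MDOF) system R(t) with per-component failure
limits η.  The quantity of interest is the probability that any
component exceeds its limit over an observation span (system failure),
and the level λ\* that is expected to be exceeded once over a longer
design horizon (return level).

The chain of approximations is:

1. All components' local maxima are interleaved into one nondecreasing-
   time vector R₁…R_N with unified limits η₁…η_N.  Because each
   element keeps its own limit, the merged record is nondimensionalized
   by R_j/η_j, and a single scaling factor λ probes all components'
   tails at once.
2. The conditional exceedance rate p_k(λ) — exceedance of the λ-scaled
   limit given k−1 preceding nonexceedances — is estimated by plug-in
   counting: the ratio of conditional exceedances to conditioning-event
   occurrences.  For small rates this is numerically indistinguishable
   from normalizing by N, but it is the direct empirical analogue of the
   conditional probability being approximated.  The conditioning window
   removes cascades of serially dependent exceedances, so that p_k
   approaches, as k grows, the rate of *independent* first failures.
3. Stationarity (the panel is assumed driven by ergodic environmental
   influences) makes p_k independent of the position j, giving the
   nonexceedance approximation P_k(λ) ≈ exp(−N·p_k(λ)).  This neglects
   Prob(R₁ ≤ η₁λ) ≈ 1 and requires N ≫ k; both hold in the regimes the
   package targets (N in the thousands, k ≤ 5).  For k = 1 it reduces to
   the classical mean up-crossing-rate relation P ≈ exp(−ν⁺T), which is
   implemented as an independent cross-check.
4. Nonstationary regimes are handled by the long-term mixture
   p_k(λ) = Σ_m q_m·p_k(λ, m) over environmental states with weights
   q_m summing to one.

Inequality conventions are fixed throughout: exceedance is strict
(R_j > η_jλ), conditioning is non-strict (R_{j−i} ≤ η_{j−i}λ); a value
exactly at the scaled limit counts as nonexceedance.

## Units and scales

All rates are "% of population per year" (0.724 means 724 deaths per
100 000).  λ is dimensionless; a rate maps to λ via the design limit η
(default 1.0 % of population), so the default fitting cut-off of 0.6 %
of population is λ₀ = 0.6.  Readers convert death counts using
deaths/population × 100.

## Maxima extraction

Two modes are provided because a 30-point annual series supports no
meaningful interior-peak declustering.  "interior" keeps samples
strictly greater than both neighbours (plateaus count once, at their
first sample; endpoints never qualify); "all_samples" keeps every annual
value.  The automatic default switches at 50 points: shorter series use
every sample, longer records use interior maxima.

## Conditioning depth

`check_k_convergence` compares consecutive curves with the relative
discrepancy max_λ |p_k − p_{k−1}| / max(p_k, 1/N) ≤ tol (default 5%).
The 1/N floor keeps deep-tail grid points — whose rates are resolved to
within one count — from dominating the comparison.  Memoryless panels
converge at k = 2 (conditioning changes nothing); strongly
autocorrelated panels may not converge within k_max = 5 at the 5%
tolerance, in which case the largest k is used and flagged, a
deliberately conservative choice (deeper conditioning only removes
cluster double-counting).

## Confidence intervals

The band p̂·(1 ± z/√n_exc) treats the exceedance count as Poisson: the
relative standard error of a rate estimated from n_exc events is
1/√n_exc.  Points with no exceedances carry no band and are excluded
from tail fitting, which prevents structural zeros from anchoring the
fit.  A coverage simulation at ≈50 expected events confirms 93–97%
empirical coverage; the band width shrinks like √2 when the record
doubles.

## Tail fit

The four-parameter sub-asymptotic class p(λ) ≈ q·exp(−a(λ−b)^c)
(a > 0, c > 0) is fitted above the cut-off by minimizing
Σ w(λ)(ln p̂ − ln q + a(λ−b)^c)² with weights w = 1/(ln ci_hi − ln
ci_lo)², normalized; equal weights are used when no bands are available
(e.g. fitting noiseless synthetic curves).  Numerical design:

- (ln q, a) enter the objective linearly and are profiled out exactly by
  weighted linear least squares at fixed (b, c); Nelder-Mead then
  searches only (b, c), from a deterministic 8-point start grid
  (c ∈ {0.5, 1, 1.8, 3} × b ∈ {0, 0.9λ₀}).
- The offset is constrained to 0 ≤ b ≤ 0.9λ₀: rates are nonnegative, so
  a negative tail offset has no physical meaning, and an offset
  approaching the cut-off degenerates the form.  The constraint also
  resolves the strong (a, b, c) ridge that otherwise makes the free
  four-parameter problem poorly identified at realistic noise levels.
- Residual ties are broken toward c closest to 1, the plain-exponential
  member of the family (when c = 1, b is unidentifiable and q absorbs
  it, so any tied solution gives the same curve).
- A two-parameter pure exponential (`form="exponential"`) is available
  as a fallback.

The same form is fitted to the lower/upper confidence series to give
extrapolated bands; where the fitted bands would cross the point fit
they are clipped to remain nested.

## Return level

The default criterion solves p(λ\*) = 1/(maxima_per_year × horizon): one
expected exceedance over the horizon.  An explicit survival probability
target exp(−n·p) = P₀ is also supported; the criterion used is recorded
verbatim in every `Prediction`.  λ\* is found by bisection on the
monotone fitted tail (relative tolerance 1e-12; validated against the
closed-form logarithmic inversion of the c = 1 family to 1e-9).
maxima_per_year is N divided by the number of distinct observation
years, so a record thinned to even years has its own rate.  Confidence
bounds on λ\* come from solving the same equation on the fitted band
curves (bracketed by the point estimate; a band whose fit never reaches
the target yields a one-sided bound).

## Synthetic panel generator

`simulate_panel` draws M AR(1) chains (coefficient ρ_t) driven by
equicorrelated Gaussian innovations (pairwise ρ_c), marginally standard
normal, then maps them through a moment-matched lognormal: σ² =
ln(1 + cv²), μ = ln(r̄) − σ²/2.  This is the simplest law with both
temporal memory (motivating k > 1) and cross-regional dependence
(motivating the merged design); a uniform-marginal hook supports exact
iid benchmarks.

Defaults emulate a worldwide annual mortality panel: M = 195 regions,
T = 30 years (1990–2019), mean rate 0.25 % of population, cv = 0.35 —
chosen so the pooled panel's observed maximum over ~5850 samples sits
near 0.7 % of population, the scale of the highest national CVD rates
on record once a single outlier country is excluded — ρ_t = 0.6
(national rates are persistent), ρ_c = 0.4, design limit η = 1 %.  A
cancer-like companion panel uses a quarter of the mean rate, matching
the fourfold limit scaling.  What the generator does **not** emulate:
persistent between-country level differences (all regions share one
marginal), age structure, reporting changes, or trends.  Passing tests
therefore demonstrate correctness of the estimation chain under a known
law, not fidelity to any particular country's epidemiology.

## Validation design

- Counting is checked exactly against a naive re-counter on random
  merged vectors (N ≤ 5000, k ≤ 5), and the worked 4-record example is
  asserted by hand.
- The memoryless limit compares exp(−N·p̄₁) with the exact F^N over
  2000 replicates.
- The end-to-end check places the failure limit at the marginal 99.7th
  percentile of an M = 5, T = 2000 panel (≈30 expected exceedances per
  record) and requires the estimator's 1 − P₃(1) to fall inside the
  2000-replicate Monte-Carlo CI of the union event.  With a single
  realized panel the exceedance count is Poisson, so the comparison is
  made where both routes are statistically determined; the binomial CI
  uses the exact Clopper-Pearson bound at degenerate replicate counts.
- Tail recovery is verified noiselessly to 1e-4 and under multiplicative
  lognormal noise (σ = 0.1), where the constrained fit recovers (a, c)
  within 20% in well over 90% of replicates.

Problem sizes throughout (N up to 10⁴, 200-point λ grids, 1000–2000
replicate simulations) were chosen as the smallest at which the
sampling-error tolerances above are meaningful.

## Known limitations

- For k ≥ 2 the conditioning event itself changes with λ, so exact
  monotonicity of p_k in λ is guaranteed by construction only for k = 1;
  small non-monotonicities at k ≥ 2 are sampling artefacts.
- The exp(−N·p) approximation is biased when applied to a single record
  with only a handful of exceedances (Jensen's inequality); predictions
  at and beyond the design limit should come from the fitted tail, not
  from the raw p̂ at λ = 1.
- The tail class is an extrapolation hypothesis; nothing in a 30-year
  record can confirm it at the 100-year level.  The confidence band
  quantifies sampling noise given the class, not model error.
- Whether input rates are age-standardized or crude is not inspected;
  the numeric column is taken as-is.
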