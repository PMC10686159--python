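# mdof-extremes

Reliability analysis and return-level prediction for panels of regional
health-outcome time series — e.g. annual cardiovascular (CVD) and cancer
death rates for every country of the world.

## The problem

A public-health system spanning many regions can be viewed as one
multidegree-of-freedom (MDOF) dynamic system: a vector process
R(t) = (X(t), Y(t), Z(t), …) of annual death rates, one component per
region, with a failure limit η_X, η_Y, η_Z, … for each component.  The
system "fails" the first time any component exceeds its limit:

    1 − P = Prob(X_T^max > η_X  ∪  Y_T^max > η_Y  ∪  Z_T^max > η_Z ∪ …)

Estimating the joint distribution of all the component maxima directly is
hopeless at 195 dimensions with 30 annual observations each.  This
package implements a merged-maxima conditional-exceedance method that
sidesteps the joint density entirely.

## The method

1. **Merge.**  The local maxima of every component are interleaved, in
   time order, into one synthetic vector R₁ … R_N carrying a unified
   limit vector η₁ … η_N (each maximum keeps its source's limit).
   Two causes per region are first combined as max(X^cvd, s·X^cancer)
   with s = 4: cancer's failure limit is lowered fourfold to match CVD's.
2. **Scale.**  A dimensionless factor 0 < λ ≤ 1 lowers all limits
   simultaneously, so the tail can be probed at levels where data exist.
3. **Count.**  The conditional exceedance rate

       p_k(λ) = Prob{ R_j > η_j λ | R_{j−1} ≤ η_{j−1} λ, …, R_{j−k+1} ≤ η_{j−k+1} λ }

   is estimated by direct counting.  Conditioning on the k−1 preceding
   maxima counts only the first failure in each cluster of dependent
   exceedances; convergence in k is checked empirically.
4. **Approximate.**  Under stationarity, the system nonexceedance
   probability over the record is  P_k(λ) ≈ exp(−N·p_k(λ)), the
   discrete analogue of the mean up-crossing-rate relation
   P(λ) ≈ exp(−ν⁺(λ)T).
5. **Extrapolate.**  Above a cut-off λ₀ the sub-asymptotic tail class
   p(λ) ≈ q·exp(−a(λ−b)^c) is fitted by weighted least squares in log
   space and inverted for the return level λ\* with one expected
   exceedance over a design horizon (default 100 years).  95% confidence
   bands follow the exceedance counts, p̂·(1 ± 1.96/√n_exc).

A synthetic-panel generator (equicorrelated lognormal AR(1) field) and a
brute-force Monte-Carlo oracle for the union failure event are included,
so every step of the chain is validated end to end without external data.

## Worked example

`python examples/tail_fit_and_return_level.py` simulates a study-scale
bivariate panel (195 regions × 30 years, cancer limit scaled fourfold)
and runs the default pipeline:

```
merged vector: N = 5850 over 30 years
conditioning depth k* = 5
tail fit above lambda0 = 0.6: p(lambda) = 0.529 * exp(-9.75 * (lambda - 1.05e-12)^1.48)

100-year return level: 0.964 % of population [0.752, 1.214]
15-year record (odd years omitted): 1.013 % [0.761, 3.614]  <- wider band from half the data
```

The return level is the annual death rate expected to be reached once,
anywhere in the system, over 100 years — just below the 1% design limit
for this panel.  Halving the record (keeping even years only) visibly
widens the confidence band, as less data must support the same
extrapolation.  The other scripts in `examples/` demonstrate the
estimator on small panels, the Monte-Carlo validation, and the
OWID-style CSV workflow.

## Real data

`read_rate_table` ingests the wide "causes of death" CSV layout (columns
`Entity`, `Code`, `Year`, one numeric column per cause, optional
population column for count→rate conversion); `exclude_components`
drops outlier regions; the same pipeline then applies unchanged.  A thin
CLI wraps the library: `mdof-extremes simulate | fit | predict |
validate`, each taking `--config` (YAML), `--seed`, `--out`, `--verbose`.

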