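"""Full study-scale analysis: merged causes, tail fit, 100-year return level.

Simulates a 195-region, 30-year bivariate panel (a CVD-like and a
cancer-like cause, the latter's failure limit lowered fourfold), runs the
default pipeline and prints the predicted annual death rate that is
expected to be reached once in 100 years, with its 95% confidence band.
"""

from mdof_extremes import RunConfig, SimulationConfig, analyze_panel, merge_causes, simulate_panel

cfg = RunConfig(seed=1)
cvd = simulate_panel(SimulationConfig(seed=101))
cancer = simulate_panel(SimulationConfig(mean_rate=0.0625, seed=202))
panel = merge_causes(cvd, cancer, cancer_scale=cfg.cancer_scale)

result = analyze_panel(panel, cfg)
pred = result.prediction
q, a, b, c = result.fit.params

print(f"merged vector: N = {result.merged.N} over {result.merged.n_years} years")
print(f"conditioning depth k* = {result.convergence.k_star}")
print(f"tail fit above lambda0 = {result.fit.cutoff}: "
      f"p(lambda) = {q:.3g} * exp(-{a:.3g} * (lambda - {b:.3g})^{c:.3g})")
print(f"\n100-year return level: {pred.rate_percent:.3f} % of population "
      f"[{pred.ci_lo:.3f}, {pred.ci_hi:.3f}]")

thinned = analyze_panel(panel, cfg.replace(thin_odd_years=True))
p15 = thinned.prediction
print(f"15-year record (odd years omitted): {p15.rate_percent:.3f} % "
      f"[{p15.ci_lo:.3f}, {p15.ci_hi:.3f}]  <- wider band from half the data")

print(
    "\nThe return level is the annual rate with one expected exceedance,\n"
    "anywhere in the system, over the 100-year horizon: the critical level\n"
    "the extrapolated exceedance-rate curve assigns to the design period."
)
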