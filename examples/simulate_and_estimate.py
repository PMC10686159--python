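"""Simulate a small multiregion panel and estimate conditional exceedance rates.

Draws 10 correlated annual rate series, interleaves their values into the
merged time vector, and prints p_k(lambda) at a few scaled threshold levels
for conditioning depths k = 1..3, together with the depth at which the
estimate stabilizes.
"""

import numpy as np

from mdof_extremes import (
    SimulationConfig,
    check_k_convergence,
    estimate_pk,
    panel_to_merged,
    simulate_panel,
)

panel = simulate_panel(
    SimulationConfig(n_components=10, n_years=30, lag1_autocorr=0.6, cross_corr=0.4, seed=7)
)
merged = panel_to_merged(panel)
print(f"merged vector: N = {merged.N} local maxima over {merged.n_years} years")

grid = np.linspace(0.3, 1.0, 8)
curves = [estimate_pk(merged, grid, k) for k in (1, 2, 3)]
print("\nlambda   " + "  ".join(f"p_{c.k}(lambda)" for c in curves))
for i, lam in enumerate(grid):
    row = "  ".join(f"{c.p[i]:10.4f}" for c in curves)
    print(f"{lam:6.3f} {row}")

conv = check_k_convergence(curves)
print(
    f"\nconditioning depth k* = {conv.k_star}"
    + ("" if conv.converged else " (not yet converged at tol = 5%)")
)
print(
    "p_k(lambda) is the probability that a merged local maximum exceeds its\n"
    "lambda-scaled failure limit given the k-1 preceding maxima did not;\n"
    "a drop from p_1 to p_2 reveals clustering of exceedances in time."
)
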