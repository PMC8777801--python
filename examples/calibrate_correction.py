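"""Monte Carlo calibration of the nearly exact discrepancy value.

Simulates the expected KL discrepancy E[F(Y_lambda)] on a reduced lambda grid,
fits the 4-parameter rational correction by multistart weighted least squares,
and compares the resulting nearly exact value 1/2 + eps(lambda) with the
classical constant 1/2.  (The full 1385-point grid at S = 1e6 takes about a
minute; this demo uses a smaller design so it runs in seconds.)
"""

import numpy as np

from tvkl import PUBLISHED_FIT, fit_correction, nearly_exact_delta, simulate_table
from tvkl.calibration import expected_discrepancy_oracle

grid = np.concatenate([np.arange(0, 121) / 20.0, np.arange(7.0, 66.0, 2.0),
                       np.arange(70.0, 255.0, 10.0)])
table = simulate_table(grid, samples=200_000, seed=7)
report = fit_correction(table, n_starts=40, seed=8)
c = report.params
print(f"fitted correction parameters (S = 2e5, {grid.size}-point grid):")
print(f"  c = ({c.c1:+.4f}, {c.c2:+.4f}, {c.c3:+.4f}, {c.c4:+.4f})")
print(f"  published (S = 5e7 reference): ({PUBLISHED_FIT.c1:+.4f}, "
      f"{PUBLISHED_FIT.c2:+.4f}, {PUBLISHED_FIT.c3:+.4f}, {PUBLISHED_FIT.c4:+.4f})")
print(f"  weighted cost {report.cost:.5g}; "
      f"{report.n_converged}/{report.n_starts} starts converged, "
      f"{len(report.local_minima)} distinct local minima")

print("\nper-level accuracy against a brute-force expectation:")
print("  lambda   true E[F]   1/2 error   nearly-exact error")
for lam in (0.2, 0.5, 1.0, 2.0, 4.0, 10.0, 100.0):
    truth = expected_discrepancy_oracle(lam)
    e_const = 100 * (0.5 - truth) / truth
    e_ne = 100 * (nearly_exact_delta(lam, c) - truth) / truth
    print(f"  {lam:6.1f}   {truth:.5f}   {e_const:+8.2f}%   {e_ne:+8.2f}%")

print("""
The constant 1/2 overshoots hugely as lambda -> 0 and sits ~10% low around
lambda in [1, 4]; the fitted rational correction stays within a fraction of a
percent over most of the range, which is what makes the nearly exact
discrepancy principle usable in the low-count regime.
""")
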