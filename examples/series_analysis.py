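"""Why the constant discrepancy value 1/2 fails at low photon counts.

Builds the exact truncated series for the expected KL discrepancy
delta(E)(lambda) = E[F(Y_lambda)] at increasing truncation orders and compares
it, at a low and a high count level, with a brute-force evaluation of the
expectation.  At high counts the series settles quickly near 1/2; at low counts
the terms grow without bound, so no truncation can stand in for the expectation.
"""

from tvkl import convergence_probability, series_coefficients, truncated_expected_value
from tvkl.calibration import expected_discrepancy_oracle

print("Exact series coefficients gamma_i^(N) (order N = 6):")
for i, g in enumerate(series_coefficients(6).gamma):
    print(f"  gamma_{i} = {str(g):>10s} = {float(g):+.6f}")

for lam in (0.8, 50.0):
    truth = expected_discrepancy_oracle(lam)
    print(f"\nlambda = {lam}: true E[F(Y_lambda)] = {truth:.6f}")
    for order in (1, 2, 3, 5, 7, 9, 11):
        approx = truncated_expected_value(lam, order)
        print(f"  order {order:2d}: truncated series = {approx:+12.4f}"
              f"   (error {approx - truth:+.4f})")
    p = convergence_probability(lam)
    print(f"  P(0 < Y <= 2 lambda) = {p:.4f}"
          f"  -> series {'cannot converge' if p < 0.999 else 'may converge'} here")

print("""
Reading the output: at lambda = 50 each extra order improves the match and the
value sits near 1/2 + 1/(12 lambda).  At lambda = 0.8 the truncations blow up
with order -- the expansion of ln(1+x) behind the series only converges on the
event 0 < Y <= 2 lambda, which at low counts has probability far below 1.
""")
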