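"""Restore a low-count blurred phantom with three discrepancy principles.

Simulates a 64x64 piecewise-constant phantom at peak count kappa = 5 (a severe
photon-starved acquisition), blurs it with a 5x5 Gaussian kernel (sigma = 1),
adds a small constant background, draws Poisson counts, and runs the DP-ADMM
solver three times: with the oracle (known-truth) discrepancy value, with the
classical constant value m/2, and with the nearly exact value.
"""

from tvkl import (
    PUBLISHED_FIT,
    AcquisitionSpec,
    DeltaSpec,
    SolverConfig,
    degrade,
    isnr,
    make_phantom,
    run,
    ssim,
)

x_true = make_phantom("piecewise_constant", (64, 64))
acq = AcquisitionSpec(kappa=5, band=5, sigma=1.0, background=2e-3, seed=1)
y, lambda_bar = degrade(x_true, acq)
model = acq.model(x_true.shape)
x_ref = acq.kappa * x_true

print(f"observed counts: min {y.min()}, max {y.max()}, mean {y.mean():.2f}")
print(f"{'rule':12s} {'mu_hat':>8s} {'iters':>6s} {'ISNR(dB)':>9s} {'SSIM':>7s}")
for name, spec in [
    ("oracle", DeltaSpec("theoretical", reference_lambda=lambda_bar)),
    ("constant", DeltaSpec("approximate")),
    ("nearly-exact", DeltaSpec("nearly_exact", params=PUBLISHED_FIT)),
]:
    cfg = SolverConfig(dp_variant=spec, tol=1e-5, max_iter=500)
    res = run(y, model, cfg)
    print(f"{name:12s} {res.mu_hat:8.4f} {res.iterations:6d} "
          f"{isnr(res.x, x_ref, acq.background):9.3f} {ssim(res.x, x_ref):7.4f}")

print("""
mu_hat is the regularization weight each rule selected.  At this count level
the constant rule targets too large a fidelity value, picks a mu that is far
too small and under-regularizes; the nearly exact rule lands close to the
oracle's mu and recovers several dB of ISNR.
""")
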