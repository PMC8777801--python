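# tvkl — TV-KL restoration of Poisson count images with nearly exact discrepancy-principle parameter selection

Photon-counting acquisitions (fluorescence microscopy, emission tomography,
astronomy) produce images whose pixels are independent Poisson counts
`y ~ Poiss(H x̄ + b)`, where `H` is a known blur operator, `x̄` the unknown
scene and `b` a constant emission background. A standard way to recover `x̄`
is the TV-KL variational model

    x̂(μ) ∈ argmin_{x ≥ 0}  TV(x) + μ · KL(Hx + b; y),

with isotropic total variation `TV(x) = Σ_i ‖(Dx)_i‖₂` and the generalized
Kullback–Leibler fidelity `KL(λ; y) = Σ_i F(λ_i; y_i)`,
`F(λ; y) = λ − y ln λ + y ln y − y` (the Poisson negative log-likelihood up to
constants). Everything hinges on the regularization weight μ.

The **discrepancy principle** picks μ so that the fidelity at the restored
image equals a prescribed value Δ. The classical choice is the constant
Δ = m/2 (m pixels), justified by `E[F(Y_λ)] = 1/2 + O(1/λ)` — accurate at
mid/high counts, badly wrong at low counts. This package provides:

- **Exact series analysis** (`tvkl.moments`): Poisson central moments as exact
  rational polynomials in λ, the truncated-series coefficients of
  `E[F(Y_λ)] ≈ Σ γ_i^{(N)} λ^{-i}`, and the diagnostic
  `P(0 < Y_λ ≤ 2λ)` showing the series cannot converge in the low-count
  regime — the constant 1/2 is not just inaccurate there, it is unfixable by
  taking more series terms.
- **Monte Carlo calibration** (`tvkl.calibration`): simulation of
  `δ(E)(λ) = E[F(Y_λ)]` on a 1385-point grid over [0, 250] and a multistart
  weighted least-squares fit of the rational correction
  `ε(λ; c) = (λ² + c₁λ + c₂) / (12λ³ + c₃λ² + c₄λ − 2c₂)`,
  which satisfies ε(0) = −1/2 and ε(λ) ~ 1/(12λ) by construction. The
  **nearly exact** discrepancy value is then `Δ(NE) = m/2 + Σ ε(λ̂_i; ĉ)`.
- **DP-ADMM solver** (`tvkl.admm`): an ADMM for the TV-KL model whose four
  subproblems all have closed forms (group soft-thresholding, non-negative
  projection, one FFT-diagonal SPD solve, and a per-pixel quadratic-root
  intensity update), with μ re-selected at every iteration by solving the
  scalar discrepancy equation `D(γ) = Δ` (theoretical / constant / nearly
  exact variants), including the sufficient-condition check that guards the
  nearly exact update.
- **Synthetic protocol and metrics** (`tvkl.synthetic`, `tvkl.metrics`):
  phantoms in [0,1], the κ-scaling + Gaussian blur + background + Poisson
  sampling acquisition model, ISNR and SSIM.

## Worked example

`python examples/restore_phantom.py` simulates a 64×64 piecewise-constant
phantom at peak expected count κ = 5 (counts mostly in 0–4), blurs it with a
5×5 Gaussian kernel (σ = 1), adds background 2·10⁻³, and restores with three
discrepancy rules:

```
observed counts: min 0, max 12, mean 1.61
rule           mu_hat  iters  ISNR(dB)    SSIM
oracle         0.9652    330    13.155  0.6999
constant       0.2681    324     8.793  0.5969
nearly-exact   1.3877    469    14.286  0.7129
```

The oracle row uses the ground truth (infeasible in practice) and marks the
target. The constant rule m/2 overestimates the discrepancy value at these
count levels, selects a μ four times too small and under-regularizes (−4.4 dB
versus the oracle); the nearly exact rule lands near the oracle's μ and
slightly above its ISNR. The other examples show the divergence of the
truncated series at low counts (`series_analysis.py`), the calibration fit
(`calibrate_correction.py`), and agreement between the in-iteration selection
and an a-posteriori fine-grid sweep (`posterior_validation.py`).

A thin CLI mirrors the library: `tvkl series`, `tvkl calibrate`,
`tvkl simulate`, `tvkl restore`, `tvkl evaluate`, `tvkl experiment`
(see `tvkl --help`).

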