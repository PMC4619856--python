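# Methods

## Model

The package reconstructs a 2D attenuation image `x ∈ R^N` (mm⁻¹, square
pixels, isocenter at the grid center) from post-log fan-beam sinogram data
`p ∈ R^M` under the penalized weighted least-squares criterion

    x* = argmin_x  Ψ(Rx) + (β/2) (p − Hx)ᵀ W⁻¹ (p − Hx).

Assumptions: a monoenergetic source on a circular orbit; a flat
(equidistant) virtual detector through the isocenter; raw counts follow a
compound Poisson + additive Gaussian model, so the log-transformed data
are approximately Gaussian with data-dependent variance; no scatter,
beam hardening, or detector crosstalk.

## Geometry and projector

View angles are measured counter-clockwise from the +x axis to the source;
physical y points up, so the image row index runs against y.  Detector bin
spacing is specified at the physical detector and rescaled onto the
virtual detector by `source_to_iso / source_to_detector`.

`H` is built by exact Siddon/Amanatides–Woo grid traversal (numba kernel):
entry `h_ij` is the length (mm) of ray `i` inside pixel `j`.  Adjointness
of `H`/`Hᵀ` is exact because both apply the same sparse matrix.  The
builder refuses geometries whose source orbit intersects the grid support.
Matrices can be cached to a single `.npz` container carrying a geometry
hash and format version; stale caches are rejected at load.

## FBP baseline

Equidistant-detector weighted fan-beam FBP: cosine pre-weighting
`D/√(D²+s²)`, convolution with the band-limited spatial-domain ramp kernel
(no apodization) via zero-padded FFT, and distance-weighted (`D²/U²`)
back-projection with linear interpolation.  The 2π orbit covers each line
twice, hence the extra factor ½.  On a noise-free 50 mm disk the interior
mean is reproduced to ~0.01%.

## Noise model and statistical weights

`simulate_transmission` draws `I = Poisson(I0 e^{−ŷ}) + N(0, σ_e²)` from a
single seeded generator over the row-major flattened ray order (one
Poisson pass, then one Gaussian pass), making results independent of the
2D layout.  Counts below 1 are clamped before the log (photon-starved
bins).  The per-bin variance of the log data is

    σ_i² = (1/I0) e^{p̄_i} (1 + (1/I0) e^{p̄_i} (σ_e² − 1.25)),

with the measured `p_i` plugged in for the unobservable mean `p̄_i`
(a smoothed estimate can be passed instead); a 1e−12 floor keeps W
invertible.  Monte-Carlo simulation reproduces this formula to well under
5% across the attenuation range used.

**Weight scale.**  At problem assembly the inverse weights are normalized
to unit maximum (`w_i = σ_i²/min σ²`).  Only the absolute scale — not the
inverse-variance ratios that carry the statistical information — is
affected; the estimator is identical up to the meaning of β.  This keeps
the data-term Hessian norm at a geometry-independent O(1e8) scale, where
the documented proper range β ∈ [1e2, 1e4] genuinely balances the two
terms and the BB step safeguards `[ρ_min, ρ_max] = [1e−10, 1e10]` contain
the spectral steps.  With raw variances (~1e−4) the data Hessian norm is
~1e12, β ≤ 1e4 leaves the penalty numerically irrelevant, and every BB
step would be clamped three orders of magnitude too large.

## Penalty and shrinkage

The penalty is evaluated in fully separable anisotropic form,
`Ψ(v) = Σ_i Φ(|v_i|)` over all 2N stacked horizontal/vertical first
differences (forward differences, zero rows at the far boundary so that
`R·const = 0` and the shape stays 2N×N).  For the ℓ1 potential this is
ordinary anisotropic TV; for the edge-preserving potential the separable
form is the member of the penalty family for which the auxiliary
subproblem genuinely decouples into scalar problems — a grouped
interpretation would forfeit the exact shrinkage update.

The scalar subproblem `min_y Φ(|y|) + (γ/2)(y − v)²` has closed forms:

* ℓ1: soft threshold `y = sign(v)·max(|v| − 1/γ, 0)`;
* edge-preserving: `y = sign(v)·(z + √(z² + 4s|v|))/2` with
  `z = |v| − s − 1/(sγ)`, derived from the stationarity condition
  `y/(s(s+y)) + γ(y − |v|) = 0` on `y ≥ 0`.

Both are validated against bounded golden-section minimization over 1000
random `(v, s, γ)` draws to better than 1e−6.

## ANAD inner solver

At fixed multiplier the augmented Lagrangian is quadratic in `x` and
separable in `y`.  ANAD alternates:

1. a gradient step `x ← x + α d`, `d = −t·∇₁L`, where `t` is the adaptive
   BB step (BB1 if the cosine between the iterate and gradient differences
   exceeds τ = 0.2, else the minimum of the last h = 3 BB2 values; clamped
   to `[1e−10, 1e10]`) and α backtracks (ρ = 0.5, δ = 1e−4) against a
   lagged reference value φ_r rather than monotone descent — φ_r starts at
   +∞ and drops to the worst recent value after K = 5 non-improvements;
2. the exact separable y-update `y = prox(Rx − λ/γ)`.

Numerical choices that the algorithm statement leaves open:

* **First step**: `t₀` is the exact Cauchy step `gᵀg / gᵀQg` of the
  quadratic-in-x Lagrangian (one extra operator application).  A
  scale-blind first step can poison the nonmonotone machinery: during the
  initial φ_r = +∞ grace period every trial is accepted, so one badly
  scaled step inflates the reference values beyond recovery.
* **Iterate invariant**: gradients are always evaluated at `y = y(x)`, the
  exact minimizer — this is what makes `∇₁L(x, y(x))` a subgradient
  surrogate for the reduced nonsmooth objective.  The inner solver
  therefore performs a y-update on entry; warm starts pass only `x`.
* **Gradient differences for BB** use the identity
  `∇₁L(x, y') = ∇₁L(x, y) + γRᵀ(y − y')`, costing one sparse matvec
  instead of a full gradient.
* Non-positive curvature (`sᵀy ≤ 0`) falls back to a clamped unit step;
  the line search absorbs the scale.

The inner loop stops at gradient norm ≤ tol (default 1e−3) or after
`max_inner_iter` (default 10) iterations — short inner loops are effective
because the outer loop warm-starts both the iterates and the BB memory.

## ALM outer loop

`λ₀ = 0`, `y₀ = Rx₀`, `x₀` = the FBP image.  Each outer iteration runs the
inner solver, then `λ ← λ − γ(Rx − y)`.  The line-search reference state
is reset after each multiplier update (the stored values describe a stale
objective); the BB memory is kept.  Termination: relative x-change below
1e−4 or an iteration cap; a guard aborts if the PWLS objective grows more
than 10× over five outer iterations.  The relative splitting residual
`‖Rx − y‖ / max(‖Rx‖, 1)` is recorded every iteration.

## Baselines

**NCG**: Polak–Ribière directions on the PWLS objective, with the ℓ1
potential smoothed as `√(t² + ε²)` (ε = 1e−6) when selected; the
edge-preserving potential is used exactly.  The initial trial step
minimizes the local quadratic model along the direction (exact data
curvature plus the pointwise second derivative of the potential), then
Armijo backtracking enforces monotone decrease; non-descent directions
restart with steepest descent.  On quadratics this reduces to CG and
reaches machine precision in ≤ n iterations — deliberately a strong
baseline.

**SB-NCG**: split-Bregman iteration — the quadratic x-subproblem
`(β/2)‖p − Hx‖²_W⁻¹ + (γ/2)‖y − Rx − b‖²` is solved by 5 inner
exact-step NCG (= CG) iterations, followed by the shrinkage update
`y = prox(Rx + b)` with threshold `1/γ` and the additive Bregman update
`b ← b + Rx − y`.

## Hyper-parameters

* `β` (data-fidelity weight): default 5e3, selected by scanning the proper
  range [1e2, 1e4] for maximal reconstruction SNR on the default benchmark
  scan — the standard empirical selection for PWLS smoothing parameters.
  The optimum is flat (4e3–7e3).  Configs outside the range trigger a
  warning, not an error.
* `s` (edge-preserving scale): default 1e−3 mm⁻¹, on the order of
  one-tenth of a tissue–lesion contrast step, so edges are preserved while
  flat-region noise is quadratically penalized.
* `γ` (splitting weight; does not change the minimizer): default 3× the
  spectral balance heuristic `λ_max(βHᵀW⁻¹H)/λ_max(RᵀR)/100`
  (`select_gamma`, power iteration with an eigenvalue-change stopping
  rule and a degenerate guard for scalar operators).  The factor was fixed
  once against the residual-vs-speed trade-off at the default scale
  (residual 2e−8 at 40 outer iterations, vs 6e−5 at 1×); because the
  heuristic tracks the Hessian scale it transfers across grid sizes where
  any fixed numeric value fails.  An explicit configured γ always wins.
* ANAD constants δ = 1e−4, ρ = 0.5, ρ_min = 1/ρ_max = 1e−10, K = 5, h = 3,
  tol = 1e−3 are the published defaults; τ = 0.2 is typical for this BB
  switching family and configurable.

## Synthetic phantom and study conditions

The licensed anthropomorphic phantom the method is usually demonstrated on
cannot be redistributed, so the fixture is an ellipse-composite head
phantom: a skull ring (0.025 mm⁻¹), brain tissue (0.0096 mm⁻¹), two
ventricles (−0.002), and three lesions at +12%, +8% and +4% of tissue
contrast, with square ROIs spanning ~80% of each lesion radius (including
a few boundary pixels so region variances stay finite) plus a uniform
background ROI.  Values sit inside the standard display window
[0.0048, 0.0128] mm⁻¹.  Noise-free sinograms come from closed-form
line–ellipse chord lengths, not from projecting the rasterized image —
avoiding the inverse crime of testing a projector against itself.

Default benchmark conditions: 128×128 grid of 1.25 mm pixels, 180 views
over 2π, 256 bins of 1.407 mm at the detector, source–isocenter 570 mm,
source–detector 1040 mm, I0 = 1e5, σ_e² = 11 — a desk-scale analogue of a
clinical 512²/1160×672 acquisition with approximately the same ray-to-pixel
ratio (~2.8), chosen so the complete four-method comparison runs in tens
of seconds on one CPU.  Consequences: published absolute SNR/MSE/CNR/UQI
values for the clinical-scale phantom are *not* reproduced — only their
orderings and convergence behavior are meaningful here, and those are what
the tests assert.

What the generator does not emulate: polyenergetic spectra and beam
hardening, scatter, bowtie filtration, detector afterglow, anatomical
texture.  Passing tests therefore validate the estimator and solvers under
the stated noise model, not clinical image quality.

## Evaluation metrics

SNR (dB) and MSE over the full grid against the rasterized truth;
CNR `|x̄_ROI − x̄_BG| / √(σ²_ROI + σ²_BG)`; UQI
`4·Cov·x̄·x̄_true / ((σ² + σ²_true)(x̄² + x̄²_true))` per ROI with sample
(Q−1) statistics.  Identical images yield an SNR of +∞ (reported as a
distinct sentinel) and UQI 1 (the 0/0 limit of identical regions is taken
as perfect similarity); other zero-denominator cases raise.

## Known limitations

2D fan-beam only (no cone-beam/3D, no curved-detector weighting); no
non-negativity constraint on x; the plug-in variance estimate inherits the
noise of single-realization data; the γ heuristic is advisory and can be a
factor of a few from the empirically best value; split-Bregman and ALM
memory cost is ~3 extra image-sized vectors per difference direction.
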