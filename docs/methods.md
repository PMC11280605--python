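# Methods

## Forward model and data

The acquisition model per saturation offset ω is g(ω) = F[A(x,ω) f(x,ω)] + n,
with f(x,ω) ≥ 0 the amplitude image, A = e^{iφ(x,ω)} a unit-modulus phase
factor, and F a *centered orthonormal* 2-D DFT (origin at the array center
via fftshift, `norm="ortho"`). The convention is shared by simulation and
reconstruction, so decode∘encode is the identity to machine precision;
any self-consistent convention would do. Noise n is i.i.d. Gaussian on the
real and imaginary parts of every k-space sample with standard deviation
σ = p·mean|g(ω₀)|, where p is the quoted noise level and the mean is taken
over the complex magnitudes of the reference-offset k-space — the only
reading of "mean k-space signal" that is positive and scale-covariant.

Amplitudes across offsets are tied by the Z-spectrum, f(x,ω) = f(x,ω₀)Z(x,ω).
The sample at the unsaturated reference ω₀ is **exactly 1 by definition**
(no RF is applied there), so the simulator sets f(·,ω₀) = s₀ identically and
pixel-wise spectral fits exclude the reference sample: it carries no
saturation information, and including it would bias the fit because the
model curve evaluated at the (far off-resonant) reference frequency is
≈0.975, not 1.

## Spectral model

The combined Lorentzian–Gaussian (LG) lineshape is

Z(ω) = 1 − a/((ω−ω₁)² + Γ) − Σᵢ bᵢ·exp(−(ω−ωᵢ)²/σᵢ²),

with a, Γ in Hz² (water), bᵢ dimensionless and σᵢ in Hz (pools). Pool
centers ω₁, ωᵢ are fixed, never fitted. The all-Lorentzian (LL) variant
replaces each Gaussian by bᵢ/((ω−ωᵢ)²+σᵢ), the pool width mirroring the
water term's form (Hz²). Pool terms are dips and are subtracted; a
`pool_sign` switch restores an additive sign for sensitivity checks, since
the subtracted form is what Z-spectra with saturation dips at the pool
frequencies require.

Fitting is bounded nonlinear least squares over {a, Γ, bᵢ, σᵢ}. Internally
the amplitudes are parametrized as dip *depths* — a/Γ for water, bᵢ/σᵢ for
LL pools — so every amplitude shares the dimensionless bound [0, 1.5]
(Z-scale data cannot support deeper dips), with Γ ∈ (0, span²], σᵢ ∈
(0, span] (span = grid extent; lower cutoffs at 5% of a grid step keep the
lineshapes resolvable). Two engines solve the same problem:

* `fit_zspectrum` — scipy trust-region-reflective least squares with an
  analytic Jacobian, for single spectra; recovers noiseless 51-point truths
  to ~1e-14 relative from ±10%-perturbed starts.
* `fit_zspectrum_map` — a vectorized Levenberg–Marquardt over all masked
  pixels at once, used inside the reconstruction loops. Positive scale
  parameters (Γ, σᵢ) are optimized in log space: this equalizes Jacobian
  column scales (depths are O(1), Γ is O(10⁴–10⁵)) and avoids the
  projection trap where a clipped overshoot pins a width at its lower
  bound. Steps are Marquardt-damped, capped at 1 per component (log units
  for scales), and accepted only on cost decrease. The two engines agree on
  noisy pixels to ≤1e-4 in the tests (a deliberate dual-route check).

Default initialization when none is given: water depth from 1 − min Z
within ±3 grid steps of ω₁, Γ₀ = (10·step)², pool depths from the residual
dip at each center, σ₀ = 3·step. Inside ADMM the previous iteration's
parameters warm-start the fit (15 LM iterations suffice; cold fits get 60).
An all-constant spectrum short-circuits to the zero-amplitude solution with
a `degenerate` diagnostic.

## Joint reconstruction

The constrained problem (README) is split with auxiliary variables
v (denoised image copy) and T (spectrum copy) and solved by ADMM on the
augmented Lagrangian with penalty ρ = 0.5 — ρ affects convergence rate, not
the fixed point. One outer iteration updates, in order, with freshest
values (Gauss–Seidel):

1. **f(·, ω≠ω₀)**: CGLS on the stacked least-squares system
   [FA; √ρ·I; √ρ·I] f = [g; √ρ(f₀T − y/ρ); √ρ(v + z/ρ)], batched over ω.
2. **f(·, ω₀)**: CGLS coupling the reference data fidelity with one √ρ·T_ω
   row per other offset — the cross-frequency information path.
3. **Z**: pixel-wise model fit to the target T + t/ρ (the calculus solution
   of the Z sub-problem before projection onto the model family), masked to
   foreground pixels; background spectra stay flat (Z ≡ 1).
4. **v**: plug-and-play denoising, per offset: v = D(f − z/ρ, λ).
5. **T**: closed form T = (ρZ − t + f₀y + ρf f₀)/(ρf₀² + ρ) (denominator
   ≥ ρ > 0 always).
6. **Duals**: y += ρ(f − f₀Z), z += ρ(v − f), t += ρ(T − Z). The y-update
   ascends on the fitted Z by default; a `dual_y_form="T"`
   switch uses the splitting variable T to match the constraint literally.

Because the DFT is unitary and |A| = 1, the image sub-problems are
well-conditioned and CGLS converges in a handful of iterations (tol 1e-6,
cap 50). The complex CGLS solutions are split into magnitude and phase:
the magnitude becomes f (hence f ≥ 0 by construction) and the phase is
folded into A once per outer iteration; pixels with numerically zero
magnitude retain their previous phase. Initialization warm-starts from the
conventional reconstruction: f, A from the per-offset FFT, Z from its
pixel-wise fit, v = f, T = Z, duals zero.

**Stopping**: both mean relative changes, mean|Δf|/mean|f| and
mean|ΔZ|/mean|Z| (Z *samples*, not parameters), below ε = 0.001, with an
outer-iteration cap (default 100; the tests and acceptance script cap at
10, which the warm start makes sufficient — noiseless runs converge in 1–2
iterations, noisy runs in 7–10). A divergence guard aborts with a
diagnostic if the data-fidelity residual grows tenfold over five
iterations. Theoretical convergence of the heuristic loop (denoiser +
fitting projection) is not guaranteed; the per-iteration history records
relative changes, fidelity residual and constraint violation so monotone
behaviour can be inspected rather than assumed.

## Plug-and-play denoising and λ

The denoiser contract is a pure deterministic map (2-D image, noise
variance λ) → image, with λ ≤ 0 meaning identity; implementations are
name-registered. The default is scikit-image's **non-local means** (patch
size 5, patch distance 6, h = 0.8σ, fast mode) — a patch-based collaborative
filter well suited to piecewise-smooth MR magnitude images; wavelet, total
variation, Gaussian-blur and identity denoisers are registered as
alternatives and as test hooks.

λ is estimated per offset from the denoiser input f − z/ρ: local variances
of all dense 5×5 patches (population variance, valid patches only), binned
into 64 equal-width bins; λ = 0.5 × the center of the tallest bin. Taking
half the mode is deliberately conservative — on a pure σ noise field the
patch-variance mode sits slightly below σ², and halving it avoids
over-smoothing structure. A constant image yields λ = 0.

## Phantoms and study conditions

`preset_spec` provides three compartment scenes, each with a smoothly
varying low-order polynomial phase (constant across ω by default; a
per-offset linear scaling is togglable since either behaviour is plausible
for a real scanner):

* **simulated_brain** — 128×128 (tests use 64×64), offsets −1250..1250 Hz
  step 50 (51 offsets), reference ω₀ = −1250 Hz, water at 0 Hz, one CEST
  pool at 450 Hz. Two tissue compartments with proton density 0.85
  (T1/T2 = 1200/120 ms carried as metadata only — the forward model never
  uses relaxation times); water line depth 0.999, Γ = 4·10⁴ Hz²
  (Z(0) ≈ 0.001), insert pool b = 0.12, σ = 150 Hz, giving
  MTR_asym(450 Hz) ≈ 0.12. These line parameters were chosen once to give
  a near-saturated water line and an asymmetry in the [0, 0.2] display
  range typical for such phantoms.
* **choline** — five vials (one water-only, four with pool amplitudes
  0.03–0.16 standing in for 10–100 mM) in a signal-free background; pool at
  130 Hz on a −650..650 Hz step-26 grid (51 offsets).
* **iopamidol** — four inserts with amide pools at 530 and 700 Hz in a
  water background; the step-50 grid is augmented with ±530 Hz so both pool
  offsets and their negations are acquired.

Choline/iopamidol pool amplitudes are illustrative defaults, overridable in
the YAML spec. Offset subsampling keeps ω₀, the water offset, and every
±pool offset, spreads the remaining retained offsets evenly, and reports
the computed reduction fraction (51→37 is 27.5%, 51→44 is 13.7%).

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: Bloch–McConnell saturation dynamics, B0/B1
inhomogeneity, relaxation-weighted contrast, multi-coil encoding, physiological
motion, and structured (non-Gaussian) scanner noise. The generator draws
spectra from the same model family the reconstruction fits, so the
end-to-end recovery results quantify the pipeline's self-consistency and
noise behaviour, not lineshape-model adequacy for in-vivo spectra.

## Evaluation metrics

SNR is 20·log₁₀(mean ROI signal / background std) per offset (amplitude
convention; a 10·log₁₀ power switch exists), averaged arithmetically over
offsets. MTR-asymmetry maps mask background pixels (reference signal below
5% of its maximum). Uncertainty reduction across ROIs is
100·(1 − mean(std_new)/mean(std_ref)) with an unweighted mean over ROIs;
because that aggregation is a convention, per-ROI reductions and their mean
are reported alongside. Contrast-to-noise of an MTR map is
(mean_ROI − mean_ref)/std_ref against a CEST-free reference region.

## Numerical choices and limitations

* CGLS stops on the normal-equation residual relative to its initial value;
  an exact initial iterate returns immediately.
* Histogram-mode λ estimation is binning-dependent (64 bins); very small
  images give noisy modes.
* Background pixels are excluded from spectral fitting but included in the
  data-fidelity solves, so background amplitudes follow the data (plus
  denoising), not the constraint.
* Magnitude images have Rician-like noise statistics after the modulus;
  no bias correction is applied, matching the conventional baseline.
* The batched LM fitter can stop at a bound (amplitude 0) for flat or
  inverted spectra; this is the intended solution for CEST-free pixels.
* Problem sizes in the test suite and acceptance script (64×64 matrices,
  10 outer iterations, 10 seeds per condition) are the package's chosen
  study conditions; larger matrices and iteration caps only change runtime,
  not any algorithmic path.
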