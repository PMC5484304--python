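# Methods

## Physical model

An RF excitation pulse p(t) of duration τ (ms) and peak amplitude p_max
(μT) produces, at a voxel with complex transmit sensitivity S(r), the
flip angle θ(r) = δ₁·p_max·τ·γ·S(r), where γ is the gyromagnetic ratio
(267.522 rad·s⁻¹·μT⁻¹ for ¹H, configurable) and δ₁ = ∫p dt/(p_max τ) is
the pulse's area relative to a block pulse. The companion factor
δ₂ = ∫p² dt/(p_max² τ) fixes the deposited energy and hence the power
duty cycle Δ = δ₂τ/TR. For any nonnegative peak-normalized envelope
δ₁² ≤ δ₂ ≤ δ₁ (Cauchy–Schwarz below, boundedness above); both factors
are intrinsic to the pulse shape. Slice-profile changes with flip angle
are ignored, which is adequate for the simple excitation pulses used
with bSSFP.

Pulses are either sampled envelopes, whose factors are computed by
trapezoidal quadrature (converging to the closed forms for block and
half-sine shapes within 1e-6 at ≥ 512 samples), or named presets that
carry stored factors. The `measured-gaussian` preset (δ₁ = 0.53,
δ₂ = 0.40) represents a truncated Gaussian excitation pulse as
characterized on a clinical 3 T system; the exact vendor
truncation/apodization is not recoverable from the nominal shape, which
is why presets store their factors rather than recompute them.

For a multi-channel system the flip-angle map is θ = S_θ w with
S_θ = θ₀·S and complex shims w. Per-channel forward power relates to
field amplitude through the RF-chain gain A (W/μT²):
peak = A(|wⱼ|p_max)², average = peak·Δ. SAR is evaluated from Hermitian
PSD Q-matrices normalized to the quadrature mode — after normalization,
quadrature drive yields mean B1⁺ = 1 μT over the slice ROI — and scaled
to absolute W/kg by B1⁺_achieved²·Δ, where
B1⁺_achieved = p_max·mean|S·w_quad| calibrates the model to measured
(here: emulated) maps.

## The nested optimization

Minimum TR at target mean flip angle is found with an outer
derivative-free search over τ and an inner constrained shim solve at
each candidate (τ, TR_min(τ)), TR_min(τ) = max(τ + t_enc, τ/δ₀).
Defaults: t_enc = 1.7 ms, gating limit δ₀ = 0.5, target θ₀ = 45°,
P_peak = 1 kW, P_av = 100 W, A = 2.5 W/μT², IEC normal-mode SAR caps of
10 W/kg (10 g local) and 2 W/kg (whole body).

**Inner solvers.** The MSE objective ‖|S_θw| − θ₀‖²_ROI and the
minimum-bias objective (mean|S_θw| − θ₀)² are non-convex through the
magnitude; both are solved as magnitude least squares by variable
exchange over the auxiliary unit phase z, initialized from the
quadrature-mode excitation phase. The fixed-z subproblem
min ‖Mw − t‖² subject to per-channel modulus caps and quadratic SAR
forms is convex (second-order-cone representable); it is solved with
SLSQP on the real/imaginary stacking of w with analytic gradients and
cap-normalized constraints, followed by a radial feasibility repair:
w = 0 always satisfies the caps, so scaling the iterate toward zero
restores feasibility exactly without a solver round-trip. The exchange
loop keeps the running-best iterate (cost is therefore nonincreasing),
stops at a relative cost change below 1e-4 or 20 exchanges, and by
default adds two seeded random-phase restarts — magnitude least squares
has local minima, and the quadrature-phase basin is occasionally not the
best one on small or unstructured problems. The scaled-quadrature
(single-channel) mode w = d·w_quad has a closed-form optimum: the
zero-bias scale clipped to the tightest cap.

**Outer search.** Nelder–Mead simplex on log τ within a bracket
(default 0.2–5 ms), initial simplex at the TR_min breakpoint
τ = t_enc·δ₀/(1−δ₀) where the encoding- and gating-limited branches
meet, at most 10 iterations for PTx modes (the cost is unimodal in
practice and the simplex contracts quickly in one dimension; quadrature
mode, whose inner solve is closed-form, is allowed up to 100), one
restart from a perturbed point if the search ends at a bracket edge.
The outer cost is TR_min(τ) in ms plus the bias penalty in squared
percent with unit weight — a violated penalty (≥ 25) dominates typical
TRs (≈ 3), giving an effectively lexicographic preference for acceptable
bias; the weight is exposed for tuning. The penalty compares |θ̂| to the
5 % tolerance (the sign of the bias carries no cost information).
Infeasible or out-of-bracket evaluations return a large finite cost
(10⁶ ms) so the search itself stays unconstrained; an inner problem with
nonpositive caps returns a typed infeasible result rather than raising.

**Accelerated mode** computes the exchange phase z only once, at the
first outer evaluation, and reuses it for all later τ candidates (a
single convex solve each). It is on by default and typically changes the
optimum negligibly while cutting runtime several-fold; a flag disables
it.

**VOPs and reporting.** Working SAR constraints use a
virtual-observation-points compression of the local Q set: candidates
are visited in decreasing spectral-norm order and dropped when an
existing VOP core V dominates them within ε·Z (PSD test with a 1e-9
eigenvalue tolerance, ties broken by original index; Z is the
spectral-norm-dominating member). Stored VOP matrices include the ε·Z
term, so the compressed maximum never underestimates the true one, with
excess at most ε·w*Zw; ε = 0 is lossless. The default working set uses
ε = 0.03. Because VOPs overestimate, the optimizer's solution can sit up
to ε below the true SAR limit; the final solution is therefore
*polished* at the optimal τ with an active-set loop over the full
uncompressed Q set (re-solving against the currently hottest ~30 voxels
until the hot set stabilizes), and all reported SAR values are
recomputed from the full set. Reported active constraints are those
within 0.1 % (relative) of their bound.

## The synthetic phantom

`synthetic_em` replaces a full-wave EM simulation and a B1⁺-mapping
acquisition with a deterministic, seeded surrogate whose purpose is to
reproduce the *structural* features the optimizer exploits, at
physically representative magnitudes:

* Geometry: a 64×64 grid of 4 mm voxels; an elliptical body (semi-axes
  90×60 mm, σ = 0.5 S/m, ρ = 1050 kg/m³) with a superficial
  high-conductivity region (0.9 S/m — a fluid/muscle mass reaching the
  surface) that makes the SAR distribution mirror-asymmetric; an
  off-center annular "myocardium" ROI whose interior "blood pool" is
  excluded from optimization, as flow corrupts B1⁺ mapping there.
* B1⁺ per channel: line-source amplitude (∝ 1/distance) from 8 elements
  at 2π/8 spacing on a 160 mm circle, exponentially attenuated beyond
  the body surface with the skin depth of the background tissue
  (≈ 63 mm at 127.7 MHz, σ = 0.5), and a phase roll −k·depth with k from
  the tissue wavelength (εr = 60), plus a reflected (standing-wave)
  component of relative amplitude 0.5. The interference of the two
  produces the characteristic 3 T center-weighted shading: the
  quadrature flip-angle coefficient of variation over the ROI is ≈ 0.19,
  matching cardiac values reported at 3 T (≈ 0.21). The transverse field
  orientation enters as a geometric phase chosen so the
  positive-increment quadrature vector is the constructive circularly
  polarized mode. Small seeded per-element gain (3 %) and phase (5°)
  jitter emulate element tolerances; the symmetric-coil reference case
  is recovered by setting both to zero.
* E-fields (surrogate, z-directed): azimuthally localized under each
  element (von-Mises-like factor, κ = 16 ≈ ±20° half-width), faster
  radial decay (1/d^2.5) and short attenuation into the load (10 mm) —
  the reactive near field of strip elements. Per-voxel Q-matrices are
  the Gram matrices σ/(2ρ)·E*E (Hermitian PSD by construction), averaged
  over the smallest centered box reaching 10 g, grown alternately by
  rows and columns so the mass overshoot stays small; the whole-body Q
  is the mass-weighted mean over the body. The represented section
  thickness is 20 mm — over the central region of 42 cm elements the
  fields are nearly z-invariant — which gives the in-plane averaging
  footprint (~22 mm) of a true 10 g cube.
* Normalization and calibration: one shared factor scales B1 and E so
  the mean quadrature |B1⁺| over the ROI is exactly 1 μT (hence scaling
  B1 by c scales every Q by c²), and the overall E amplitude is set so
  the peak 10 g local SAR of quadrature drive at 1 μT mean and unit duty
  cycle equals `sar_efficiency` = 9 (W/kg)/μT². That value places a 45°
  bSSFP protocol in the SAR-limited regime of whole-body transmit arrays
  (quadrature optimum near TR ≈ 4.7 ms, whole-body SAR ≈ 1 W/kg when
  local SAR reaches 10 W/kg).

What the surrogate does *not* capture: full-wave propagation and
tissue-interface refraction, 3-D anatomy and inter-subject variability
(body size enters only through the geometry parameters), coil
tuning/matching/decoupling, and transverse E components. Tests passing
on this phantom therefore demonstrate the correctness and the
qualitative sequence-level behavior of the optimization — constraint
integrity, SAR scaling laws, the PTx-versus-quadrature TR and
homogeneity advantage and its growth with target flip angle — not
quantitative SAR prediction for any real subject.

`emulate_b1_measurement` adds circular complex Gaussian noise (default
SD 0.02 μT per unit drive, ≈ 2 % of the quadrature mean) and returns the
sensitivities on the blood-pool-excluded ROI, i.e. exactly the maps an
in-vivo mapping acquisition would feed the optimizer.

## Numerical choices and degenerate inputs

* SLSQP: ftol 1e-12, ≤ 300 iterations, warm-started from the previous
  exchange iterate (first start: the largest feasible scaled-quadrature
  point). The fixed-z solve never returns an iterate worse than its
  feasible start.
* Solutions are re-verified against the uncompressed constraint set at
  1e-6 relative; the radial repair guarantees this bound structurally.
* Quadrature closed form agrees with a 1-D bisection oracle to 1e-12.
* Zero-amplitude shims make the coefficient of variation undefined; this
  raises a typed error rather than returning NaN. Single-voxel ROIs are
  allowed (for tests) with a warning.
* Degenerate phase (|S_θw| = 0 at a voxel) maps to z = 1 in the
  exchange update.
* All randomness (phantom jitter, measurement noise, restart phases) is
  seeded; identical inputs give identical outputs.

## Problem sizes

The default phantom yields 1052 local Q-matrices (≈ 160 VOPs at
ε = 0.03). A full three-mode comparison at these sizes runs in a few
seconds on one CPU; the solver-versus-grid oracle tests use 2-channel /
12-voxel instances where an exhaustive 201×201×201 polar grid search is
tractable as an independent reference.

## Known limitations

* The inner solver is a general NLP method on a convex problem, not an
  interior-point cone solver; for much larger arrays (≥ 32 channels) or
  VOP sets in the thousands, a dedicated SOCP solver would scale better.
* Magnitude least squares is non-convex; the exchange with restarts
  finds the global optimum on all tested instances but carries no
  guarantee.
* The bias penalty's unit weight ties percent² to ms; protocols with
  TRs far from ~3 ms may want a different weight.
* Temperature constraints, short-term (10 s) SAR averaging windows,
  multi-slice joint shimming and phase-only shimming are out of scope.
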