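# Methods

## The inverse problem and the hierarchical model

MEG/EEG source reconstruction seeks the current dipole moments
Q = (q_1, …, q_n), q_j ∈ ℝ³, at n fixed source locations from an m-channel
measurement b = M Q + ε, where M ∈ ℝ^{m×3n} is the lead field and
ε ∼ N(0, Σ).  With m in the hundreds and n in the tens of thousands the
problem is severely underdetermined, and plain minimum-norm solutions are
biased toward superficial sources.

`iasmeeg` implements a conditionally Gaussian hierarchical model:

- q_j | θ_j ∼ N(0, θ_j C_j), with C_j = ν_j ν_jᵀ + δ(I − ν_j ν_jᵀ) the
  anatomical prior block favoring the preferred direction ν_j
  (δ ∈ (0, 1] is the transversal relative variance, default 0.05);
- θ_j ∼ Gamma(β, θ*_j), with shape β = η + 5/2 shared across dipoles.

Writing ‖v‖²_A = vᵀA⁻¹v, the joint MAP estimate of (Q, Θ) minimizes the
Gibbs energy

    E(Q, Θ) = ½‖b − MQ‖²_Σ + ½ Σ_j ‖q_j‖²_{C_j}/θ_j
              − η Σ_j log θ_j + Σ_j θ_j/θ*_j ,

which is globally convex, so the alternating scheme below has a unique
fixed point.

## Sensitivity weighting and automatic scaling

The only required user input is an SNR estimate (signal power over noise
power, > 1).  The hyperprior scales are set by exchangeability — every
dipole configuration of equal support size should be a priori equally able
to explain a signal of the given SNR — which yields

    θ*_j = P (1 − 1/SNR) / (β ‖M_j C_j^{1/2}‖²_F),

computed through the factor-free identity ‖M_j C_j^{1/2}‖²_F =
trace(M_j C_j M_jᵀ), hence independent of the choice of matrix square
root.  P is estimated as the mean squared column norm of a user-designated
data window (the full data set by default); this estimator is unbiased for
stationary segments and keeps the contract simple.  An optional quantile
cutoff clips (not deletes) the largest θ*_j — clipping preserves the
source-space size and keeps indexing stable; the quantile uses linear
interpolation between order statistics so the cutoff is bit-reproducible.

Before solving, the lead field is scaled so its largest per-dipole block
has unit Frobenius norm, and the data so that the median column norm is
√m.  When only an SNR is given, homoscedastic noise Σ = σ²I is assumed
with σ² = P/(SNR·m), making trace(Σ) = P/SNR consistent with the SNR
definition; a full SPD covariance may be supplied instead and is whitened
through its Cholesky factor.  Scalings are undone on output, and the
reconstruction is invariant to a joint rescaling of (b, M, Σ).

η lives with the hyperprior scales (in `HyperModel`, not in the solver
configuration) because θ* depends on β = η + 5/2; choosing η after
computing θ* would silently decouple the two.

## The alternating solver

Starting from Θ = Θ* (or a warm start), each outer iteration performs:

1. **Dipole update.**  Minimize E over Q at fixed Θ.  With
   C_Θ = diag(θ_j C_j) = D_Θᵀ D_Θ and whitener W (WΣWᵀ = I), the
   substitution Q = D_Θᵀ w turns this into min_w ‖y − Aw‖ with
   A = W M D_Θᵀ, y = W b, solved by CGLS from w = 0.  The right
   preconditioner built from the prior factor makes the Krylov iterates
   explore prior-plausible directions first; the iteration is stopped
   early by the discrepancy principle — at the first iterate with
   ‖y − Aw_k‖² ≤ m, the expected energy of whitened noise — which plays
   the regularizing role of the prior penalty, typically within a few
   tens of lead-field products.  A stagnation guard (relative residual
   decrease < 1e-12) prevents non-termination on rank-deficient systems,
   and `max_it` (default 120) caps the count; hitting the cap flags the
   diagnostics but is not an error.
2. **Variance update.**  The Θ-minimization is separable with the closed
   form θ_j = θ*_j (η/2 + √(η²/4 + ‖q_j‖²_{C_j}/(2θ*_j))), whose floor
   η·θ*_j is attained exactly at q_j = 0.

The loop stops when the relative Euclidean change ‖Θ^{k+1}−Θ^k‖/‖Θ^k‖
falls below τ (default 0.01) or after `n_outer` (default 30) iterations.
The Euclidean norm was chosen for the stopping metric for scale
stability; the same metric is reported in the diagnostics.

For *exact* energy minimization (used by the validation suite to confirm
convergence to the global minimum) the configuration flags
`explicit_penalty=True` with `inner_stop="max-only"` switch the inner
solve to damped CGLS (unit damping in the priorconditioned coordinates),
which includes the prior penalty ½‖w‖² explicitly and runs to numerical
convergence.  With exact inner solves the energy is non-increasing across
outer iterations and the fixed point matches a brute-force minimizer to
~1e-10 relative; the early-stopped run-time path trades this exactness
for speed and data-adaptive regularization.

For time series, slice s > 1 can be initialized at the variance estimate
of slice s−1 (`warm_start`, default on): activity changes little between
adjacent samples, so the previous variances are a good starting guess and
the outer loop typically needs fewer iterations.  Non-finite data columns
are recorded per-slice and skipped without aborting the run; the slice
after a skipped one falls back to a cold start.

## Parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `snr` | required | signal power / noise power, must be > 1 |
| `eta` | 0.01 | focality: 1e-4 very sparse … 0.1 distributed; 0.001 for focal sources |
| `delta` | 0.05 | transversal relative variance of the anatomical prior |
| `cutoff_quantile` | 1.0 | quantile for clipping θ*; 1.0 = no clipping |
| `tau` | 0.01 | outer tolerance on relative Θ change |
| `n_outer` | 30 | outer iteration cap |
| `max_it` | 120 | inner CGLS iteration cap |

## Synthetic forward model

The generator emulates an MEG experiment with no external data:

- **Source space**: a Fibonacci lattice on a 7 cm sphere (quasi-uniform;
  nearest-neighbor spacing has coefficient of variation < 0.5), rotated
  by a seed-dependent rotation.  Orientations are outward radial (mimics
  cortical normals of a quasi-spherical surface) or tangential.
- **Sensors**: radial magnetometers on a 10 cm sphere.
- **Forward model**: the closed-form field of a current dipole in a
  spherically symmetric conductor.  Radial dipoles are magnetically
  silent in this geometry (verified to ~1e-16 relative), so recovery
  scenarios use tangential orientations; the radial field outside the
  conductor equals the radial field of the primary dipole alone, which
  the tests exploit as an independent cross-check.
- **Activations**: a contiguous patch (a seed-chosen dipole and its
  nearest neighbors, default 5 dipoles) with moments along the preferred
  orientations and a smooth Hann-window time course; amplitude 10 nA·m,
  a typical evoked-response dipole strength.
- **Noise**: i.i.d. Gaussian sensor noise with trace(Σ) = P/SNR
  (default scenario SNR 15); optionally correlated noise with a supplied
  covariance, or background "brain noise" projected from random dipoles.

What the generator does **not** emulate: realistic cortical folding and
the resulting orientation structure, BEM/FEM volume conduction, sensor
gradiometry, temporally correlated or heteroscedastic noise, and
inter-subject anatomical variability.  Passing recovery tests therefore
demonstrates the solver's correctness and its focality/depth-weighting
behavior under the model's own assumptions, not clinical localization
accuracy on real recordings.

Default validation problem sizes — 400 dipoles, 60 magnetometers,
5-dipole patches, 10 seeds, 20-slice time courses, and 20 random
3-dipole problems for the brute-force comparison — were chosen so each
check isolates one property at sizes where the independent oracles
(dense least squares, coordinate descent, exhaustive scans) are
themselves trustworthy.

## Visualization

The source space is split into ten equal-thickness layers along the
chosen axis (boundaries c_min + ℓ(c_max − c_min)/10); intervals are
half-open with the maximal coordinate closed into the top layer, so the
layers partition the dipoles exactly.  Full-brain views render ten panels
per axis on a shared color scale; single-slice views show the three
orthogonal layers through a chosen point with a marker at its
projections.  Intensities are normalized per rendered frame (the color
scale spans [0, max a_j] of the plotted slice); ten layers is the
default but is a parameter.  Axis semantics are x = right, y = front,
z = crown; inputs with other conventions should be permuted on load.

## Numerical choices and edge cases

- Local frames complete ν deterministically: the coordinate axis least
  parallel to ν is orthogonalized against it (ξ), and ζ = ν × ξ closes a
  right-handed frame.  Any completion yields the same C_j since
  ξξᵀ + ζζᵀ = I − ννᵀ; determinism and right-handedness are enforced so
  factors are reproducible across runs.
- Zero-norm or non-finite orientations are rejected, not defaulted —
  silent substitution would hide upstream segmentation errors.
- δ = 1 is accepted as the isotropic special case C_j = I.
- Zero data gives the exact fixed point Q = 0, Θ = ηΘ* in two outer
  iterations.
- The solver itself is deterministic; all synthetic randomness flows
  through one integer seed.

## Known limitations

- No posterior uncertainty: the solver returns the MAP point only.
- The EEG forward model is not generated synthetically; EEG users must
  supply a lead field computed elsewhere (the solver itself is
  modality-agnostic).
- MAT-file support is read-only and assumes the documented dataset names.
- The discrepancy threshold assumes the supplied SNR/covariance is
  trustworthy; a badly misestimated SNR shifts the regularization.
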