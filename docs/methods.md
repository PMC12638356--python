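# Methods

## Problem and signal model

Myelin water imaging estimates, per voxel, the fraction of the transverse
signal decaying with short T2 (~10–40 ms, water trapped between myelin
bilayers) relative to the total — the myelin water fraction (MWF) — and the
geometric mean T2 of the intra-/extra-cellular water peak (IET2).  Both
derive from the multi-echo spin-echo decay

    |S_x(j)| = sum_t  s_{t,x} · EPG(E, T2_t),      s_{t,x} >= 0,

where EPG(E, T2) is the Extended Phase Graph prediction of the echo
amplitudes of a CPMG train with echo times E and refocusing flip angle FA,
and T2_t runs over a geometric grid — by convention 40 points from 15 to
2000 ms (a 13.4% step).  MWF is the spectral mass at grid entries 1–8
(up to ~36 ms) over the total; IET2 is the mass-weighted geometric mean of
entries 9–21 (~40.9–184.4 ms).

The EPG simulation uses a 90° excitation and constant-angle refocusing about
an axis 90° from excitation (CPMG condition), tracks configuration states up
to order n_echoes + 1, and includes T1 decay of longitudinally stored
(stimulated-echo) pathways.  T1 is not identifiable from the data and is
fixed at 1000 ms (white-matter convention), configurable.  Longitudinal
regrowth between pulses is neglected: trains are short relative to TR.  The
implementation is validated against a brute-force isochromat rotation-matrix
oracle to ~1e-15 at arbitrary flip angles.

A gradient-and-spin-echo (GRASE) train adds n_ge gradient-recalled readouts
at time offsets Δ_j (default ±2.5 ms) around each spin echo.  Their signal is

    S^GRASE_x(j) = S^MSE_x(j) · exp(−|Δ_j| R2'_x + i ΔB0_x Δ_j),

with R2' the reversible dephasing rate (1/s) and ΔB0 the local field offset
(stored in rad/s; configuration files take Hz and convert once at parse
time).  Spin-echo samples (Δ_j = 0) are untouched.

## Acquisition configurations

One readout position of the 3D scan is treated at a time: the problems are
2D over the phase-encode plane (PE1 × PE2), with a centered, orthonormal FFT
(DC at index ⌊N/2⌋).  The forward model per coil c and echo is
μ_c = U ∘ F C_c S with binary mask U and sensitivity C_c.

* **AG0** (conventional accelerated GRASE): the two gradient echoes and the
  spin echo of each spin-echo period fill disjoint PE2 bands of one shared
  composite k-space (spin echo central), and the same mask is used in every
  echo.  The banding contributes a factor n_ge+1 = 3 of the overall
  acceleration R; the per-k-space mask density is (n_ge+1)/R.
* **AG1**: same banding, but the mask differs per echo — either a
  CAIPIRINHA lattice cyclically shifted by one position per echo, or a
  Halton low-discrepancy point set dealt round-robin across echoes.
* **AG2**: every readout gets its own k-space, each undersampled by the full
  R.  All three configurations acquire N·J/R lines in total.

CAIPIRINHA factorizes R = R1 × R2 (R1 ≤ R2, inter-row shift 1).  Halton
masks use bases (2, 3) with floor-scaling to grid cells; a point colliding
with an already-sampled cell of the current echo is skipped.  Because echoes
are filled round-robin in sequence order, mask sets at different R are
nested — convenient for monotonicity analyses.  A fully sampled central
patch (default 12 × 12) can be forced into every echo for calibration.

## Reconstruction

Echo images are constrained to a low-dimensional subspace, S = α Φ, with
Φ (d × J) the leading right singular vectors of a dictionary of candidate
evolutions:

* the model dictionary — EPG curves over the T2 grid crossed with flip
  angles 120°–180° (B1 variation); for AG2 additionally modulated over 30
  log-spaced T2' (=1/R2') values in 10–1000 ms and 200 ΔB0 values in
  ±150 Hz (±20 Hz after field compensation), subsampled to a seeded random
  20 000 tuples when the cross product is larger;
* the patch dictionary — per-voxel evolutions of low-resolution echo images
  from the fully sampled central patch.

Atoms are l2-normalized before the SVD so no parameter cell dominates; the
decomposition is computed exactly from the J × J Gram matrix.  The
coefficients solve the maximum-likelihood least-squares problem

    α̂ = argmin_α Σ_c ‖Z_c − U ∘ F C_c (α Φ)‖²,

by conjugate gradients on the normal equations from zero initialization
(relative tolerance 1e-6, 200 iterations default; the problem is linear and
convex, so the solver choice affects only runtime).  The noise level scales
the objective but not the minimizer and is carried only as metadata.  No
regularization is added by default (an optional Tikhonov weight exists).
The fully sampled reference reconstruction is the inverse FFT followed by
the sensitivity-weighted combination Σ_c conj(C_c) x_c / Σ_c |C_c|².

Two phase corrections mirror standard GRASE practice:

* **Navigator (zero-phase-encode) correction**, AG0/AG1: the per-echo phase
  profile along the readout axis, estimated from a projection navigator, is
  removed from every line of that echo in hybrid space.  Only the component
  of the B0-induced phase separable along that axis is correctable; the
  in-plane remainder is the characteristic residual artifact of composite
  GRASE sampling.
* **Patch-based field compensation**, AG2: low-resolution echo images from
  the central patch (Hann-apodized, zero-filled) are coil-combined; phase
  increments between readouts within each spin-echo period, wrapped to
  (−π, π], are fitted per voxel by least squares to a single angular
  frequency ω (the linear-phase model, refocused at each spin echo).  The
  conjugate phase ω·Δ_j is applied in the image domain (equivalently a
  k-space convolution), or passed into the forward operator for exact
  modelling of undersampled data.  On smooth ±150 Hz fields this removes
  >90% of the gradient-echo phase excursion, after which the compact ±20 Hz
  dictionary regime applies; the compensated-regime dictionary captures
  strictly more energy at every subspace size.

## Spectrum fitting

Magnitude spin-echo decays are fitted voxel-wise by non-negative least
squares against the EPG design matrix.  B1 correction searches refocusing
angles 120°–180° (1° default step) with plain NNLS and keeps the
minimum-residual angle (ties toward the largest); the final spectrum is
refitted with Tikhonov-regularized NNLS whose weight is chosen by bisection
so the chi-square misfit is 1.02× the unregularized minimum.  For separated
(AG2) reconstructions only the spin-echo subset enters the fit by default.
Voxels outside the ROI, or with negligible total mass, are flagged NaN.

## Synthetic data generator

The generator emulates one central slice of a brain acquisition:

* an elliptical head with a grey-matter rim (5% myelin water at ~20 ms, 95%
  at ~90 ms), white-matter interior (15% at ~20 ms, 85% at ~80 ms) and CSF
  ventricles (single ~1500 ms component), with per-tissue proton-density
  scaling — plausible-literature values, configuration defaults rather than
  measured claims;
* smooth order-2 polynomial ΔB0 (span ±150 Hz) and R2' (5–25 1/s) maps;
* 4–8 smooth complex coil sensitivities (Gaussian lobes around the FOV with
  low-order phase), band-limited by construction;
* complex Gaussian noise of chosen σ per real/imaginary channel added at the
  sampled k-space locations only; every draw is governed by one seed.

A vial phantom (disjoint single-T2 circles) emulates a relaxometry
calibration object.  The generator does not model slice profiles, diffusion,
magnetization transfer, motion, physiological noise, or compartmental
frequency shifts; passing tests therefore demonstrate correctness of the
pipeline under the stated signal model, not performance on scanner data.

## Observed behaviour and limitations

On the synthetic slice the pipeline reproduces the qualitative pattern the
method is known for.  IET2 maps are robust: at R = 3 (composite sampling,
first-echo SNR ≈ 100) the white-matter IET2 RMSD is ~5 ms, within 10 ms up
to R ≈ 12.  MWF maps are much more fragile: at the ±2.5 ms gradient-echo
offsets a ±150 Hz field offset contributes up to ~2.4 rad of phase, and in
composite (AG0/AG1) sampling only its readout-axis-separable part is
correctable by the navigator, so the gradient-echo bands remain inconsistent
with the spin-echo band.  The resulting few-percent image-domain artifact is
amplified roughly tenfold by the ill-conditioned spectrum split, leaving a
white-matter MWF RMSD of ~0.03–0.08 even noiselessly (seed-dependent), plus
~0.035 of NNLS noise at SNR 100.  With the field and reversible dephasing
zeroed the same pipeline recovers MWF to ~0.02, and with truth inside the
subspace the reconstruction is exact to solver tolerance — the error is a
property of composite GRASE sampling under field inhomogeneity, not of the
solver.  Degradation is monotone in R for nested masks.

Scale choices: simulations use one 64 × 64 readout position with 6 coils
and a 32-echo train (96 readouts for AG2); map fits default to a 4°
flip-angle search step in the experiment harness (1° in the reference
fitting configuration).  These sizes are the package's defaults for desk
experiments and are configurable.
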