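# Methods

This note documents the models, numerical choices and limitations behind
`duonuc`. The package simulates an interleaved sodium/proton 3D-radial MRI
acquisition with parallel-transmit proton excitation, end to end, on
synthetic data.

## Projection ordering and readout model

Projection directions use the two-dimensional golden-means construction:
for projection n, z_n = 2·frac(n·λ₁) − 1 (half projections, full sphere) or
z_n = frac(n·λ₁) (full projections, upper hemisphere — the negative-k half
of a center-through readout covers the antipodal ray), and
φ_n = 2π·frac(n·λ₂). The constants are λ₁ = 1/ψ² and λ₂ = 1/ψ with ψ the
supergolden ratio (real root of x³ = x² + 1), conventionally quoted
truncated to 0.4656 and 0.6823. The full-precision values matter: with the
truncated rationals the sequence is periodic (period 10 000) and directions
repeat exactly; with the irrational constants no two of 60 000 directions
coincide and any spherical cap receives its expected share of directions to
within counting statistics. The hemisphere convention for full projections
is an assumption — the construction is stated here because the quoted
sources give only the constants.

The radial readout is specified directly as k(t): uniform k-space speed g
out to k₀ = k0_fraction·kmax, then density adaptation with
k²·dk/dt = const, i.e. k(t) = (k₀³ + 3k₀²g(t−t₀))^{1/3}, reaching kmax at
the end of the readout. g follows in closed form from (kmax, t_RO,
k0_fraction). Gradient hardware limits (amplitude, slew) are deliberately
not modeled; the readout lives purely in k-space vs time. `k0_fraction`
defaults to 0.2 and is exposed because the optimal trade-off between
low-k sampling density and high-k SNR efficiency is application-dependent
(the concentration-recovery checks use 0.4, which samples low k more
finely and makes broad-compartment mean levels quadrature-accurate).

Full (center-through) readouts require an odd sample count so the k = 0
sample exists exactly once; the even case is rejected rather than given an
arbitrary convention.

**Density compensation** is analytic: each sample owns the spherical-shell
volume between the |k| midpoints to its radial neighbors, divided by the
number of rays covering the sphere of directions (n for half projections,
2n for full; the single center sample of a full readout owns the k = 0
cell of both its rays). The weights sum exactly to the volume of the kmax
ball, so the weighted adjoint NUFFT approximates the inverse Fourier
transform. In the uniform region this reduces to the familiar ∝ k²
weighting, in the density-adapted region to a constant per unit time, and
at k = 0 it is finite and positive.

## Nonuniform Fourier transform

No NUFFT library is part of the dependency set, so the transform is
implemented in `duonuc.nufft` with two paths:

* an exact chunked direct summation (separable per-axis phase factors),
  used automatically for small problems (≤ ~2.7·10⁸ voxel·sample products);
* Kaiser–Bessel gridding with 2× oversampling, kernel width 6 (Beatty's
  shape parameter), relative accuracy ~2·10⁻⁵. Deapodization uses the DTFT
  of the integer-sampled kernel, which makes the forward/adjoint pair exact
  transposes of each other to machine precision (verified by an inner-product
  test); accuracy against a brute-force DFT oracle is tested at 10⁻³ and in
  practice is ~10⁻⁵.

The convention is S(k) = Σ_x m(x)·e^{−2πi k·x} with x in mm (voxel centers,
grid center at the physical origin) and k in 1/mm.

## Phantoms and coil fields

Phantoms are painter's-ordered ellipsoidal compartments voxelized by a
center-in-ellipsoid test, carrying magnetization density (∝ concentration
for sodium, proton density for ¹H), T1 and T2*. Defaults: a homogeneous
300 mM torso ellipsoid for the in-vitro-like scenario; for the cardiac
scenario an in-vivo-like blood pool at 140 mM inside a myocardial shell at
43 mM (illustrative placeholder values — the physiological blood plasma
sodium level and a typical myocardial tissue level; no measured
compartment concentrations are asserted). Sodium T2* decay is
mono-exponential; the bi-exponential decay of in vivo sodium is a known
limitation.

Coil fields are phenomenological, not electromagnetic: the purpose of the
package is exercising the processing and optimization mathematics.

* The sodium volume coil is one channel with a smooth linear + quadratic
  taper toward one corner; the `asymmetry` parameter scales the drop-off
  depth, and the central-ROI CV is continuous and monotone in it, so a
  target homogeneity (e.g. CV 0.09 for an undisturbed coil vs 0.15 with a
  second array present) can be dialed in by 1D root finding.
* The proton array has 4 anterior + 4 posterior loop-like channels:
  exponential magnitude decay from each loop center, a smooth spatial phase
  ramp, and per-channel phase offsets spread evenly over 2π so that the
  unshimmed (all-zero-phase, vendor-like) combination interferes
  destructively mid-torso — the synthetic analogue of the cardiac signal
  dropout that motivates pTx. A seeded `phase_jitter` perturbs channel
  positions/phases to synthesize shim-library "subjects".

What passing tests on these phantoms does *not* show: robustness to real
coil geometries, tissue heterogeneity, B₀ off-resonance, or motion — none
of which are modeled.

## Sequence and signal model

Both nuclei follow a spoiled-GRE steady state
S = M₀ sin α (1−E₁)/(1−cos α E₁) · e^{−TE/T2*}, E₁ = e^{−TR/T1}. T2* decay
is applied as a single factor at the echo time, not per readout sample —
readout-duration blurring of short-T2* species is therefore not simulated.
The interleave schedule nests n (default 4) proton excitations into each
sodium TR; the proton TR pattern is (TRₐ, …, TRₐ, TR_b) with
TR_b = TR_Na − (n−1)·TRₐ absorbing the sodium block. Whether the long TR
comes first or last is not determined by the timing identity, so it is
configurable (`aaab` default, `baaa` available). The forward simulator
evaluates the steady state with the voxelwise flip angle from the applied
pTx pulse, weights by each receive field, samples with the NUFFT, and adds
seeded i.i.d. complex Gaussian noise per channel. Nuclei are independent
(no cross-talk), which is the mechanism behind the interleaved vs
single-nuclear equivalence: both schedules produce bit-identical
per-nucleus data for the same seed, mirroring the empirical finding that
interleaving does not degrade either image.

Time-averaged RF power per channel assumes rectangular hard pulses into a
matched 50 Ω load: P = duty · U²/(2Z), checked against a 1.195 W per-channel
limit.

## Flip-angle and field mapping

* Double-angle: FA = arccos(S₂α/2Sα); long-TR assumption (the protocol's
  TR 250 ms sodium mapping), T1 bias ignored. Voxels with |ratio| > 1 or
  zero denominator are masked.
* AFI: with n = TR_long/TR_short and r = S_short/S_long (the signal whose
  excitation follows the short delay over the one following the long
  delay), FA = arccos((rn − 1)/(n − r)). The protocol table labels the TRs
  with the long one first, opposite the common convention, so the API keys
  on (tr_long, tr_short) explicitly. The inversion is first-order in TR/T1;
  against an exact two-TR Bloch steady-state oracle the residual bias is
  < 0.35° over 10–85° at T1 = 1000 ms, TR 75/15 ms.
* Receive mapping: B₁⁻ ∝ S/sin FA, defined only up to scale (the
  proportionality constant is not specified by the method), so maps are
  normalized to mean 1 over the valid mask; FA outside [5°, 175°] is
  masked to avoid the sin blow-up.
* Transmit efficiency: η = FA_rad/(2πγ·T_pulse·U_applied), reported in
  nT/V.
* Relative channel maps use the sum of channel magnitudes as reference
  (map_c = img_c / Σ|img_c|), an explicit assumption standing in for the
  unstated reference of the measured relative-mapping method.
* FA simulation is small-tip: FA(x) ∝ |Σ_c w_c B₁c⁺(x)| for a shim and
  |Σ_k T_k (Σ_c w_{k,c} B₁c⁺(x)) e^{2πi κ_k·x}| for kT-points. Angles
  beyond 180° are outside the model's validity and masked, not clipped.

## pTx pulse design

The cost for all pulse families is the CV of the combined |B₁⁺|
(equivalently of the normalized flip-angle map, by small-tip linearity)
over the ROI. This is a documented surrogate: the measured-system
optimizers are not restated by their publications, but CV is the reported
homogeneity metric throughout, so optimizing it directly is the natural
desk-scale choice.

* DPS is a fixed, configurable phase vector (all zeros by default —
  vendor phases are proprietary); on the synthetic array it produces the
  mid-torso dropout by construction.
* IPS/UPS: multi-start Nelder–Mead over n_ch − 1 phases (first channel
  fixed to 0 as the global-phase gauge), deterministic given the seed. A
  tiny (10⁻⁴-weighted) transmit-efficiency bonus breaks ties such as the
  single-voxel ROI, where CV is identically zero; it can perturb the
  achieved CV by at most that weight. UPS minimizes the library mean of
  per-subject CVs with the same structure, so a single-subject library
  reproduces IPS exactly. On 2-channel instances with ≤ 4 voxels the
  optimizer matches an exhaustive 1° phase grid to < 10⁻³ in cost.
* 4kT: K = 4 sub-pulses, complex weights by variable-exchange magnitude
  least squares (Tikhonov-regularized, regularization scaled by ‖A‖²_max so
  the design is invariant to field scaling), blips chosen greedily from a
  candidate set of 0 and ±1 cycle/FOV per axis. The target is the absolute
  field-time integral corresponding to `target_fa_deg` at a 1 V reference,
  which makes weights scale as 1/c when fields scale by c. Initialization
  from the phase shim with zero blips, and acceptance of strictly improving
  steps only, guarantee CV(4kT) ≤ CV(IPS).
* Reference-voltage calibration: ordinary least squares of voltage on body
  weight (defaults 9.4 V/kg, 542.5 V intercept from a 35-subject
  calibration), with the mean relative absolute deviation as its quality
  metric.

## Evaluation metrics

SNR maps use the Rayleigh correction SNR = (S/std_noise)·√((4−π)/2), where
std_noise is the standard deviation of magnitude-only noise scans; both the
raw magnitude std and the Gaussian-equivalent σ are exposed because the
printed formula is ambiguous about which is meant. CV uses the population
(not sample) standard deviation — a deliberate, test-locked choice; at ROI
sizes of hundreds of voxels the difference is far below any decision
threshold. Relative difference maps exclude zero-denominator voxels and
report their count.

## Problem sizes and determinism

The demonstration pipeline and acceptance computations run on scaled-down
problems chosen as the package's own working sizes: 24³–32³ grids,
hundreds to thousands of projections, with radial sample counts always
keeping the maximum radial k-step below 1/FOV so the quadrature resolves
the object spectrum (an undersampled readout produces a characteristic
center-depressed, background-lifted reconstruction — this is a property of
the data, not the transform). The timing arithmetic is exact and uses the
full protocol counts (15 000/60 000 projections etc.), since it involves no
simulation. Every stochastic component (noise, optimizer restarts, library
synthesis) is seeded; the demo report is bit-identical across reruns with
the same seed.

## Known limitations

No B₀ inhomogeneity or off-resonance; no motion or gating; no per-sample
relaxation during readout; mono-exponential sodium T2*; phenomenological
coils (no SAR fields — the power check is a per-channel time-averaged
surrogate); no iterative or compressed-sensing reconstruction; rigid
translation only, no deformable registration. Absolute CV/SNR levels on the
synthetic phantom are not comparable to in vivo values; orderings and
formula-level identities are the validated outputs.
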