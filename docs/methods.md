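# Methods

## The problem being modeled

Variable-flip-angle (VFA) relaxometry estimates T1 and T2 from steady-state
SPGR and balanced-SSFP acquisitions at several flip angles, fitted with a
single-pool signal model. Brain tissue is not single-pool: a semisolid
("bound") proton pool exchanges with free water and is partially saturated
by RF power. Since each flip angle — and each vendor's pulse shape — puts a
different RMS B1 into the tissue, the bound pool is saturated differently
in every measurement, and the single-pool fit converts that inconsistency
into protocol- and vendor-dependent parameter biases. Constant-saturation
(CSMT) pulses remove the inconsistency by delivering every flip angle at
the same RMS B1, using off-resonance side bands to top up the power.

This package simulates that mechanism end to end on a digital phantom and
quantifies it with the same statistics used for in-vivo multi-scanner
comparisons.

## Signal models

**Single-pool SPGR** is the Ernst steady state
S = M0·sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR/T1), with ideal spoiling.
TE is identical for all images (3.5 ms), so the TE decay is constant and is
absorbed into the fitted M0; it is never modeled explicitly.

**Single-pool bSSFP** is computed as the exact fixed point of the per-TR
affine recursion: excitation about the x-axis rotated by the cumulative RF
phase, free precession by 2π·Δf·TR, T1/T2 relaxation, and demodulation by
the transmit phase. With a constant phase increment Δφ the recursion is
time-invariant in the demodulated frame (per-TR precession angle
θ = 2π·Δf·TR − Δφ) and the steady state is obtained by a 3×3 linear solve
(Cramer's rule, vectorized over voxels). The echo is sampled at TE = TR/2
with e^(−TE/T2) decay and e^(+i2πΔf·TE) phase. One sign convention is
declared here and shared by the simulator and the fitting model. The
magnitude is periodic in Δf with period 1/TR; the complex signal is
antiperiodic because of the TE phase factor. An iterative Bloch propagator
(`bloch_propagate_oracle`) implements the same recursion step by step and
serves as the independent reference in tests (agreement ≤ 1e−8 relative).

**RF-spoiled SPGR** is simulated with an ensemble of isochromats uniformly
dephased over 0–2π per TR (ideal gradient-spoiling moment, deliberately not
harmonized between simulated vendors) driven by the quadratic schedule
φₙ = φ₀·n(n+1)/2 with the receiver phase-locked to the transmit. The
ensemble runs for at least ~9 longitudinal time constants; for compartments
with T2 of the order of T1 (CSF) the ensemble magnitude remains
quasi-periodic rather than settling, which the simulator flags, and a
late-window mean is used as the representative level. In the acquisition
simulator, RF-spoiling imperfection enters as a multiplicative factor
(isochromat signal / ideally spoiled signal), interpolated over a B1 grid
per tissue compartment — the factor is a property of the free pool, so it
composes with the two-pool steady state below.

**Two-pool MT models.** The generative model is a binary spin bath: free
pool (T1f, T2f, M0f) exchanging with a bound pool of equilibrium fraction
F = M0b/M0f at rate k_f (free→bound), with k_b = k_f/F by detailed balance.
The bound pool has no observable transverse magnetization; its relevant
property is the absorption lineshape G(Δ, T2b) — super-Lorentzian by
default (Lorentzian and Gaussian available), with the on-resonance pole
handled by evaluating |Δ| < 1 kHz at 1 kHz. RF saturation acts at the
TR-averaged rate ⟨W⟩ = Σ_bands π γ² ⟨B1²⟩_TR G(Δ_band), applied as a
discrete factor exp(−⟨W⟩·TR) at each pulse (instantaneous-saturation
approximation, appropriate for a fixed-RMS-B1 design target). Between
pulses the longitudinal pair (Mzf, Mzb) evolves by the matrix exponential
of the coupled exchange–relaxation system. SPGR keeps only the
longitudinal pair (2×2 fixed-point solve, ideal spoiling); bSSFP keeps the
free transverse components as well (4-state affine map, batched 4×4
solve). At F = 0 the bound pool and exchange are disabled and both models
reduce to the single-pool forms to machine precision — this reduction is
tested, and a local transmit scale b1 multiplies both the flip angle and
(quadratically) ⟨W⟩.

Because the on-resonance band is evaluated at the 1-kHz lineshape cutoff
while the side bands sit at 6 kHz, equal total power does not mean exactly
equal ⟨W⟩: as the flip angle grows, power shifts from the side bands into
the on-resonance band, where G is ~3× larger. The CSMT condition therefore
retains a small residual cross-protocol spread (~2–3% in WM-median T1 at
the defaults) rather than collapsing to zero — consistent with the few
percent residual variability reported for real CSMT acquisitions.

## Pulse design

Pulses are stored band-by-band (sampled envelope in µT plus a carrier
offset per band) rather than as a pre-modulated composite waveform; the MT
model consumes per-band power at per-band offsets, so no modulation phase
convention needs to be invented. The CSMT designer scales the base
envelope (2.5-ms Gaussian, ±3σ truncation, 250 samples — refinement
changes the power by < 1e−6 relative) to the requested flip angle, then
gives the two symmetric ±6 kHz bands equal amplitudes carrying the
residual power so that √((1/TR)·Σ∫|B1|²dt) equals the 1.6 µT target
exactly. If the on-resonance band alone exceeds the power budget the
design fails with the minimum achievable RMS B1 in the error. Vendor
excitation pulses have fixed duration and FA-scaled amplitude: hard 0.3 ms
(A), hard 0.1 ms (B), and a 1.6-ms truncated-Gaussian stand-in for vendor
C's shaped pulse — only its duration and envelope power matter to the
saturation bookkeeping.

## Phantom and acquisition simulation

The phantom is a nested-ellipsoid "head": GM shell, WM bulk, CSF core on a
1-mm isotropic grid (default 64³ — a small head, large enough for stable
WM statistics at a fraction of full-brain cost). Default two-pool
parameters (configuration choices representative of literature qMT values,
not measured facts): WM T1f/T2f = 1100/45 ms, F = 0.15, k_f = 4 s⁻¹,
T2b = 12 µs; GM 1600/70 ms, F = 0.08, k_f = 2.5 s⁻¹; CSF 4000/1800 ms,
single-pool. B1 maps span [0.85, 1.15] and B0 maps ±60 Hz as smooth
low-order polynomial fields — a diagonal-dominant linear ramp plus a small
quadratic term, a construction whose voxel-to-voxel step is bounded below
1% of the range at 64³ by the coefficient constraints. Noise is Rician
(magnitude of complex Gaussian), with the default std set for SNR 100 on
the median WM signal of the 15° SPGR — a high-quality 3D acquisition.
Test/retest replicates share truth and fields and differ only in noise
seeds. Noise seeds derive from (vendor, replicate) but not from the
acquisition condition, so native / harmonized / CSMT runs are paired on
identical noise and condition orderings are not noise races.

The three acquisition conditions mirror the study design: `native`
(vendor pulses, vendor spoiling increments 150°/50°/115°),
`harmonized_spoiling` (vendor pulses, 50° everywhere), and `csmt` (CSMT
pulses, 50° everywhere). The assignment of native increments to vendor
letters follows list order and is configurable.

## Fitting (JSR)

All SPGR and bSSFP magnitudes of a flip-angle subset enter one bounded
nonlinear least-squares problem per voxel for (M0, T1, T2, Δf), with
shared M0. Magnitudes — not complex data — are fitted, since phase
conventions are not comparable across vendors; Δf is then identified only
up to sign and period by the two phase cycles of the 45° bSSFP, and is
reported as the principal value in [−1/(2TR), +1/(2TR)), with wrap-aware
comparison in tests. T1 and M0 are initialized by the DESPOT1
linearization (S/sin α regressed on S/tan α), T2 at 80 ms, and Δf is
multistarted at 4 equally spaced points over its period; the best final
cost wins, ties broken toward the smallest |Δf|. Bounds: T1 ∈ [100, 6000]
ms, T2 ∈ [5, 3000] ms, M0 > 0. A subset must contain at least one SPGR
and two bSSFP volumes (one at the 180° increment) or fitting is refused.

Two routes implement the same problem: `jsr_fit_voxel` wraps
`scipy.optimize.least_squares` and is the per-voxel reference;
`jsr_fit_volume` runs a vectorized projected Levenberg–Marquardt
(finite-difference Jacobians, per-voxel damping, bound clipping) over all
masked voxels simultaneously, which makes 64³ studies tractable on one
CPU. The two routes are tested against each other. Fits are deterministic:
no randomness enters, and the multistart order is fixed. The fitting model
assumes ideal SPGR spoiling even though the simulated data carry
RF-spoiling imperfection — deliberately, since that model mismatch is part
of the mechanism under study.

## Statistics

WM masks come from the ground-truth labels (no segmentation is simulated)
and are eroded by a 2-mm-radius discrete sphere to mimic the
partial-volume guard used on real data. Medians summarize the WM
distributions (robust to their skew). Variability between two medians is
100·(mᵢ−mⱼ)/(0.5·(mᵢ+mⱼ)); deviation of each median from the grand mean
is 100·(mᵢ−m̄)/m̄ (zero-sum by construction); worst-case variability is
the largest absolute pairwise variability, attained at the extreme
medians. Because worst-case groupings can be read two ways, both are
computed and labeled: `cross_protocol` (across subsets within a vendor,
maximized over vendors), `cross_vendor` (across vendors within a subset,
maximized over subsets), and `global` (all vendor × subset cells).
Voxelwise variability maps between vendor pairs and between test/retest
replicates are summarized by their distribution median (center offset)
with fixed-width histogram bins.

The six flip-angle subsets are configuration (S1 = all measures; S2–S6
drop different SPGR/bSSFP combinations, all satisfying the
identifiability rule). The full study runner fits a deterministic random
subsample of the eroded WM mask (default 3000 voxels; 600 in the test
suite) — the statistics are medians, for which a few hundred voxels
already give sub-percent stability, and this keeps a full three-condition
study on one CPU in minutes.

## What the phantom does and does not show

The phantom reproduces the *mechanism*: with native variable-power pulses
the fitted T1/T2 depend strongly on the flip-angle subset and vendor pulse
duration, harmonizing the spoiling increment alone barely helps, and CSMT
pulses restore subset- and vendor-invariance to the few-percent level,
with same-vendor test/retest essentially zero-centered throughout. The
absolute sizes of the native-condition biases depend on the assumed
two-pool parameters and are larger here than typical in-vivo reports
(the phantom is pure WM/GM/CSF with no partial volume, registration error,
coil-profile or motion effects, and its two-pool WM is homogeneous), so
passing tests validate directions and CSMT-condition bounds, not the
native-condition magnitudes. Under CSMT the fitted T1/T2 are *apparent*
single-pool values — biased relative to the free-pool truth by design —
so acceptance is on reproducibility statistics, not on recovering T1f.
Receive-coil differences between vendors are absorbed into M0. B1 maps
are inputs; the accuracy of B1 mapping techniques is out of scope, as are
k-space simulation, parallel imaging, slice-profile effects, and qMT
parameter estimation.

## Numerical choices

* bSSFP steady state by exact linear solve; no iteration error.
* Isochromat ensembles: 256 isochromats (refinement-converged well below
  0.1%), ≥ max(800, 9.2·T1/TR) TRs.
* Super-Lorentzian integral by adaptive quadrature with the fiber-angle
  pole declared to the integrator; 1-kHz on-resonance cutoff.
* Bound-pool T1b fixed at 1000 ms (standard convention; the steady state
  is insensitive to it).
* Batched LM: relative finite-difference steps of 1e−6 on scaled
  parameters, multiplicative damping (×0.3 on success, ×4 on rejection),
  gradient stop 1e−10, 60 iterations, bound projection by clipping.
* Degenerate inputs fail loudly: non-positive times, empty or fully
  eroded masks, zero pair means, unidentifiable subsets, infeasible pulse
  designs (with the minimum feasible RMS B1 named).
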