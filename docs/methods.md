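# Methods

This note documents the models, numerical choices and limitations behind
`glymphflow`. It is written for a reader who wants to know exactly what the
package computes and why the defaults are what they are.

## The transport model

Dynamic contrast-enhanced (DCE) MRI of an intrathecally infused gadolinium
tracer yields a sequence of 3D frames. After conversion to percent signal
change from a pre-contrast baseline, the frame intensity is treated as
proportional to tracer density ρ. Between each pair of adjacent frames
(ρ₀, ρ₁) the solver estimates per-substep velocity fields v₀…v_{m−1}
minimising a Benamou–Brenier-type kinetic energy with the endpoint
constraint relaxed into a quadratic penalty:

    E(v) = m · Σ_k ⟨ρ_k, |v_k|²⟩ + β · ‖ρ_m − ρ₁‖²,
    ρ_{k+1} = (I − σL)⁻¹ T(v_k) ρ_k

T(v) is a mass-preserving push-forward: every voxel's mass is deposited at
its displaced position with trilinear weights, displacements clamped inside
the domain. L is the 7-point Laplacian with zero-flux (Neumann)
boundaries, so one substep is advection followed by an implicit diffusion
step — an advection-diffusion constraint rather than pure advection. The
diffusion term is the point of the regularisation: tracer redistribution
explicable by diffusion alone must not be attributed to bulk flow, and the
dedicated discrimination test checks exactly this (a diffusion-only phantom
recovers a small fraction of the speed of an advective phantom producing a
comparable frame-to-frame change).

With velocity in voxels/substep and the kinetic weight m (the m substeps
span a unit pseudo-time horizon), a rigid translation by d voxels costs
exactly mass·|d|² — the squared Wasserstein-2 distance between translated
profiles. This anchors the energy scale and is verified against the
closed form on translated Gaussians.

Internal units are voxels and substeps; speeds are converted only at
reporting: speed[μm/s] = |v|[vox/substep] · voxel[mm] · 1000 · m /
frame_interval[s].

### Optimisation

Gauss–Newton with exact adjoint gradients through the m substeps. The
adjoint of the push-forward is trilinear interpolation at the displaced
positions; the velocity gradient needs the spatial gradient of that
interpolant, with components zeroed where displacements were clamped. The
GN normal equations (kinetic diagonal + JᵀJ of the mismatch, plus a small
Levenberg damping relative to the kinetic diagonal) are solved by
Jacobi-preconditioned conjugate gradients; steps are safeguarded by Armijo
backtracking. The adjoint gradient matches central finite differences to
better than 1e−4 relative (it is exact up to floating point away from
cell/clamp boundaries).

A single strong penalty (β=1e4) pulls the early iterates onto kinetically
inefficient transport: on the translated-Gaussian benchmark the converged
kinetic energy overshoots the Wasserstein value by ~70%. The solver
therefore applies continuation on β — four homotopy stages at β·10^{k−3},
k=0…3, each warm-started from the last — which keeps the iterates near the
efficient (geodesic) flow; the same benchmark then lands within ~5% of
mass·|d|² and pathlines recover ~93% of the planted displacement. The
quadratic endpoint penalty always under-transports slightly; this is the
main known bias of the method and is visible as recovered speeds a few
percent below truth. The energy log is non-increasing within each stage
(stage boundaries are recorded in the solution object; raising β between
stages necessarily resets the energy scale).

The implicit diffusion solve (I − σL)x = b is diagonalised exactly in the
DCT-II basis (the eigenbasis of the Neumann Laplacian on a regular grid);
a conjugate-gradient route solving the same SPD system to a configurable
tolerance is available (`diffusion_solver="cg"`) and agrees with the
spectral route to solver tolerance. Mass is conserved to machine
precision by both advection (deposit weights sum to 1) and diffusion
(Neumann row sums), which the tests assert at 1e−8 relative over 40
substeps.

Key solver defaults (`RomtConfig`): σ = 0.002 voxel²/substep, β = 1e4,
m = 8 substeps/pair, 32 outer iterations across 4 continuation stages,
15 inner CG iterations, Armijo contraction 0.5. There are no canonical
values for these constants; they are this package's own choices,
recorded in every output's provenance. The solver contains no randomness;
identical inputs give bitwise-identical outputs on one platform.

### Pathline post-processing

Seeds are the centres of in-mask voxels whose first-frame density exceeds
10% of the in-mask maximum (a package choice; the threshold is exposed
in `GladConfig`). Trajectories are
integrated by one RK4 step per substep through the trilinearly
interpolated, piecewise-constant-in-pseudo-time velocity, concatenated
across intervals, positions clamped to the grid. A pathline is retained
("binarised") when its net start-to-end displacement is ≥ 0.5 voxel —
again a package choice, exposed in config. A rigid-rotation field (which
trilinear interpolation represents exactly) closes an orbit over 64 RK4
steps with <1% radius drift, fixing the integrator's accuracy scale.

Speed maps deposit each retained pathline's per-step speed (|v| at the
point, in μm/s) into the voxel containing each RK4 endpoint; a voxel's
value is the arithmetic mean of its deposits (order-independent and
tie-free). Segments crossing a voxel between endpoints are not
rasterised — a documented simplification. From the speed map:
mean solute speed = mean of strictly positive in-mask voxel speeds
(averaging over voxels, not pathline samples; the alternative reading of
"average of all positive speed values" would weight long pathlines more),
and v-flux = visited in-mask volume in mm³. Velocity flux vectors are the
start-to-end displacement of each retained pathline.

## The phantom generator

The generator emulates the study's acquisition geometry at desk scale:
32³ voxels at 0.3 mm isotropic, frames every 300 s, a ~100-minute window
(5 frames by default), a Gaussian bolus in percent-change units
(amplitude 30%, σ 0.9 mm), and velocity fields of four kinds (zero,
constant, rigid rotation, band-limited random). Bulk-flow magnitudes are
specified in mm per frame interval; the default 0.3 mm/interval equals
1 μm/s, the order of the measured CSF solute speeds (0.2–0.4 μm/s at the
circle of Willis). The additive Gaussian noise default is 1.0
percent-change unit (~3% of bolus amplitude) — no measured percent-change
noise level is available to copy, and this is a realistic DCE SNR; noise is
additive Gaussian on percent-change values, not Rician on magnitude,
because the pipeline consumes percent-change images.

To keep recovery tests honest (no inverse crime), the forward simulation
never uses the solver's transport operator: it integrates
∂ρ/∂t + ∇·(ρv) = σΔρ with an explicit conservative first-order upwind
scheme on a 2× spatially refined grid with CFL-limited substeps (≥4 per
frame interval), zero-flux boundaries, then block-averages to the
requested resolution. Against closed forms, the simulated diffusion
matches the analytic heat kernel to <2% L2 and the advected centroid moves
at exactly v (upwind advection preserves the first moment for constant v).
The scheme's numerical diffusion biases recovered speeds slightly low, on
top of the penalty under-transport.

The phantom carries a "brain" compartment mask — the noise-free
tracer-occupied region (any frame ≥ 10% of bolus amplitude) dilated by
2 voxels — the closed-skull analogue of the anatomical mask a real study
applies. Masked analysis matters at realistic noise: the pathline seed
threshold (10% of in-mask maximum) sits near the noise floor, so an
unmasked analysis seeds thousands of rectified-noise voxels whose
spurious speeds dominate the mean. Even masked, noise biases recovered
speed *upward* (speed is a convex function of velocity, so incoherent
fitted jitter adds magnitude), opposing the penalty's under-transport
bias; at 10% noise the net error on the bulk-flow phantom is ~30%.

An optional box subregion with a velocity multiplier (`RegionScale`)
plants a regional contrast; the two-cohort study uses a 1.5× subregion,
mirroring the measured ~50% regional speed difference, on 16³ grids with
3 frames so that a full 10-subject study runs in minutes on one CPU.

The synthetic ICP trace is baseline + respiratory sinusoid + cardiac
sinusoid + optional drift + Gaussian noise at 10 kHz; defaults follow the
measured physiology (4.22 Hz cardiac ≙ 253 bpm, 0.73 Hz respiratory ≙
44 bpm, baseline 5 mmHg, amplitudes 0.25/0.4 mmHg giving the measured
~0.5/0.8 mmHg peak-to-peak values). The synthetic lymph-node curve is a
gamma-variate y = A·τ^α·e^{α(1−τ)}, τ = (t−t₀)/(t_peak−t₀), peaking at
exactly t_peak (87 min, amplitude 0.13 AU, matching the measured dcLN
kinetics). The shape parameter is fixed at α = 6 — inside the classical
3–7 range for first-pass tracer curves and sharp enough to reproduce the
single-frame TTP precision observed between animals.

What the generators do **not** emulate: MRI physics (coil sensitivity, T1
relaxivity, Rician magnitude bias), anatomy (no rat-brain geometry, no
distinct CSF/tissue compartment dynamics), head motion, ICP waveform
harmonics beyond the fundamentals, or inter-subject anatomical
variability (cohort subjects differ only by noise seed). Passing recovery
tests therefore demonstrate the correctness of the estimation machinery
under the stated model, not robustness to everything real data contains.

## ICP waveform analysis

The respiratory channel is a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 2 Hz; the pulse channel is a 45-point
Savitzky–Golay smooth (order 3; the 45-sample window spans 4.5 ms at
10 kHz) followed by a zero-phase 4th-order Butterworth high-pass at
5 Hz. The cutoffs and window length follow the protocol standard in
rodent ICP studies; the filter family and orders are this package's
choices.

Because the cardiac fundamental (~4.2 Hz) lies below the 5 Hz high-pass
corner, the cascade attenuates the pulse wave by a known, computable
factor (~0.2× for a 4th-order zero-phase filter). Measured pulse
pressures are therefore divided by the cascade's transfer-function
magnitude at the estimated cardiac frequency (dominant periodogram peak
above 3 Hz). For a narrow-band pulse wave this restores the amplitude
exactly; for broadband waveforms it is first-order. The correction is a
config flag (`amplitude_correction`, default on); without it the absolute
pulse pressures are systematically low while baseline-normalised ratios
remain unbiased.

Respiratory cycles are delimited by troughs of the respiratory channel
(prominence ≥ 0.5 × channel RMS); the respiratory delta is the per-cycle
max−min ("2 Hz delta channel" read as per-cycle max−min of the 2 Hz
low-passed signal). Pulse pressure is the max−min over consecutive
windows of one cardiac period. Epoch summaries restrict to the first 10
respiratory cycles, take 1-second-interval means of the amplitude
channels (not the raw channels), and divide treatment by baseline per
subject, so the baseline row is identically 1.

## TSC kinetics

Node curves are the mean in-VOI signal per frame, divided by the maximum
of the subject's CSF curve (max vs mean is a config choice, recorded in
provenance). Denoising is a trailing 2-point moving average stamped at
the later time (trailing alignment, a package choice), so the output is
one point shorter. Time-to-peak and peak magnitude are read from the smoothed normalised curve (so peak and TTP come from the
same denoised signal), ties broken to the earliest time; AUC is trapezoidal.

## Voxel-wise statistics

Subject speed maps (assumed aligned; atlas normalisation is out of
scope) are smoothed at 0.4 mm FWHM with the
same reflective-boundary Gaussian as preprocessing, then compared with a
pooled-variance independent two-sample t test per voxel, reported as
one-sided p maps in both directions with df = nA+nB−2. Voxels with zero
pooled variance are excluded and flagged. "Significant" masks are the
two-sided test at α split by direction (one-sided p < α/2), which keeps
the null false-positive fraction at ≈ α; as is common in voxel-wise
small-animal studies, no multiple-testing adjustment is applied by
default, and a Benjamini–Hochberg FDR mask is available as a labelled
extension. The
inclusion rule (all in-mask voxels, minus zero-variance exclusions) is a
package choice.

## Degenerate inputs and tie-breaks

Percent-change voxels with non-positive baseline are zeroed and flagged.
Before the solver, frames are clamped at ≥0 and offset by a density floor
of 1e−4 × series maximum (OMT needs positive mass; noise produces small
negatives). FWHM 0 smoothing is the identity. A flat ICP trace yields
empty amplitude series rather than an error; an all-zero speed map yields
mean speed 0 and v-flux 0. Peak ties in TSCs resolve to the earliest
time. If the rOMT line search cannot accept any step, the v = 0 solution
is returned with a warning.

## Problem sizes

The default benchmarks run on one CPU: the translated-Gaussian solve
(32³, m = 8) in about a minute; the 5-frame end-to-end recovery in a few
minutes; the 10-subject planted-contrast study (16³, 3 frames) in a few
minutes; ICP/TSC analyses in seconds. These sizes are the package's
desk-scale study conditions; grids, frame counts and solver budgets are
all configurable upward.
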