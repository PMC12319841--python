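# Methods

## Model overview

The simulator propagates an ensemble of classical magnetization vectors
through a discrete voxel phantom.  Each spin carries a position (um), a
magnetization 3-vector with equilibrium (0, 0, 1), and a current substrate
label looked up from the voxel mesh.  Per time step `dt` the loop applies, in
this fixed order: random walk, ideal dephasing events, gradient plus
off-resonance precession (with relaxation folded into the same sub-step),
hard RF pulses, and echo/trajectory recording.  RF and gradients are never
applied within the same sub-step.  Echoes are complex transverse sums
`sum_s (mx + i my)`, recorded in total and split two ways per substrate: by
the label at echo time and by the label at t = 0.  Both splits are kept
because "extravascular contribution" is ambiguous once walls are permeable;
with impermeable walls they coincide.

Assumptions inherited from this class of simulator: hard (instantaneous) RF
pulses on the diffusion time grid; off-resonance from a static stored map
(no blood-cell dynamics, no flow, no spin replenishment when walkers leave a
compartment); no surface meshes — geometry lives entirely in the label
array.

## Magnetization operators and sign conventions

* RF: right-handed rotation by the flip angle about the transverse axis
  (cos phase, sin phase, 0); a 90-degree pulse about +x takes (0,0,1) to
  (0,-1,0).
* Precession: positive phase for positive field offset, rotation of
  (mx, my) about +z.
* Relaxation: transverse scaling exp(-dt/T2); longitudinal recovery
  `mz -> 1 + (mz - 1) exp(-dt/T1)`, using the T1/T2 of the substrate the
  spin occupied at the start of the step.

Neither handedness nor the precession sign is observable in any reported
quantity (all are magnitudes or magnitude ratios); they are fixed here for
reproducibility.  Whether relaxation precedes or follows the RF rotation
within one step is an O(dt/T2) ~ 1e-3 choice per step; it is applied with the
precession sub-step, before RF.

## Cylinder phantoms and the susceptibility field

Vessels are infinite cylinders placed one at a time with axis points uniform
in the box until the voxelized occupied fraction first reaches the target
blood volume fraction (BVF).  Orientations: a fixed unit vector, isotropic
random, or "perpendicular" (uniform azimuth in the plane orthogonal to B0).
Overlaps are allowed (union labeling); the generator fails loudly if the
target BVF is not reached within a bounded number of placements.  BVF is
measured on the voxel mask, not analytically, because the simulator sees
only the mesh.

The field of one cylinder uses the two-branch closed form (see README) with
the 2*pi prefactor and dchi in cgs units (0.11 ppm default) kept exactly as
conventionally printed; dchi_SI = 4*pi*dchi_cgs.  Maps are composed by
superposition at voxel centers and stored as float32 at B0 = 1 T with
oxygenation factor (1-Y) = 1; at run time the map is multiplied by
B0 * (1-Y_state), which is exact because the field is linear in both.  For a
voxel inside one or more cylinders, the first containing cylinder (placement
order) contributes its interior term, other containing cylinders contribute
nothing (their exterior form diverges as r -> 0 and their interior term
would double-count), and all non-containing cylinders contribute exterior
terms.  This overlap rule is a documented convention; overlap regions are a
small fraction of the vessel volume at the BVFs studied.

An independent finite-perturber solver (`dipole_fieldmap`, FFT convolution
with the k-space dipole kernel 1/3 - kz^2/k^2, optional zero-padding to
suppress wrap-around images) validates the analytic map; agreement in the
exterior region is ~1% RMS at the tested geometry and is asserted < 5% in
the tests.  The FFT solver is an oracle only, never the simulation path.

## Random walk, permeability, boundaries

Steps are i.i.d. Gaussian per axis with sd sqrt(2 D dt), D taken from the
substrate at the step's origin (the destination's D is unknown until the
step is proposed; the paper-gap choice is documented here).  A step whose
destination voxel belongs to a different substrate j is accepted with
probability P_ij; on rejection a fresh step is drawn for the same time step,
up to `max_redraw = 100` times, after which the spin rests in place for that
step.  Rest events are counted and reported; in all experiments shipped here
they are zero or negligible.  The redraw cap is a termination guarantee the
underlying scheme leaves unbounded.

Boundary conditions are global per run: periodic (coordinate-wise modulo) or
reflect (mirror about the violated face).  Excursions longer than one FoV
would indicate an insane time step and raise instead of wrapping twice.
Known model behavior, reproduced deliberately: with unequal diffusivities
and permeable walls, walkers slowly accumulate in low-diffusivity regions;
no correction is applied.

Virtual FoV scaling: a phantom with native FoV L reinterpreted at scale c
behaves as a box of size cL with all geometric lengths (including radii)
scaled by c.  Internally positions stay in native units and the step is
divided by c; the stored field map is reused unchanged.  A radius sweep from
one phantom sets c = R_target / R_built per point.  When the native-unit
step exceeds one voxel edge the sweep warns: walkers can then cross small
vessels in a few steps and under-sample the local field.

## Sequences

Timelines are dt-gridded event lists; TE/TR snapping to the grid is a hard
error, never a silent rounding.  Builders:

* GRE: 90x at 0, echo at TE.
* SE: 90x at 0, 180y at TE/2, echo at TE.
* bSSFP: pulses every TR with phase incremented by the phase-cycling angle,
  `n_prep` preparation TRs before the single recorded echo at TE = TR/2.
  The train starts with a full-angle pulse (no alpha/2 catalyzation);
  after a preparation span of ~5 T1 the steady state is insensitive to the
  start, which the closed-form check (0.1%) confirms.
* GRASE: 90x, then `n_se` perfect 180 pulses with alternating +/-y phase at
  odd multiples of half the echo spacing; echoes every half-spacing give
  2 n_se + 1 records, even-numbered echoes coinciding with the spin-echo
  refocusing points ("gradient" echoes are recorded time points; no readout
  gradients are played, consistent with ideal refocusing).
* STE: 90x -- tau -- 90y -- Tm -- 90y with the primary spin echo at 2 tau
  and the stimulated echo at 2 tau + Tm.  Pathway selection uses the ideal
  dephasing mechanism in place of crusher gradients: a span-2pi ramp
  immediately before and after the second pulse, a span-4pi spoiler in the
  mixing period (after the primary echo), and a span-2pi rephasing ramp at
  the stimulated echo.  The spans are chosen so that, counting each ramp as
  +/-1 unit of phase-history, only the stored (longitudinal) pathway
  returns to zero net phase at the echo: the doubled spoiler is what
  prevents the transverse-throughout pathway (conjugated once by each
  90-degree pulse) from being accidentally rephased.  For static spins in a
  uniform field this reproduces the classic amplitudes Ns/2 exp(-2tau/T2)
  and Ns/2 exp(-2tau/T2) exp(-Tm/T1) to machine precision.

Ideal dephasing distributes phase deterministically across the ensemble
(spin s of Ns gets span*s/Ns), so a 2pi span nulls a uniform ensemble's
transverse sum exactly and remains refocusable through the phase history.

## BOLD contrast and analysis

Rest and active states are two runs differing in the oxygenation factor
(field scale) and the state-dependent T2 list, sharing the random seed.
Sharing the seed (common random numbers) leaves each state's signal
distribution untouched but cancels most walk-sampling noise in the contrast
`1 - S_rest/S_active`; it is what makes desk-scale sweeps resolvable at 1e4
spins.  Contrasts: percent change 1 - S_rest/S_active and the per-spin
difference (S_active - S_rest)/Ns (the latter preserves T1-driven amplitude
effects, e.g. the stimulated echo's decline with mixing time).  Radius-sweep
peaks are reported as the grid argmax with its neighboring grid interval; no
interpolation.  Confidence intervals over repeated phantom realizations use
mean +/- 1.96 std/sqrt(n).

## Synthetic data: what it does and does not emulate

The random-cylinder generator reproduces the standard study conditions of
this literature: 4% (1-6%) BVF, radii of order 1-75 um, perpendicular or
random orientations, oxygenation 78%/85%, dchi = 0.11 ppm, B0 = 9.4 T,
D = 1 um^2/ms, dt = 50 us.  It does not emulate real microvasculature:
no branching networks, no diameter distributions, no pial/penetrating
hierarchy, no flow or volume changes, and intravascular fields ignore the
dipolar dynamics of moving blood cells.  Passing tests therefore validate
the signal-formation machinery on the cylinder model, not quantitative
agreement with in vivo measurements.

## Numerical choices and problem sizes

* One PCG64 generator per run, seeded from the config seed; identical seeds
  give bit-identical results (tested).
* Field maps float32 (values ~1e-7 T; relative rounding ~1e-7), magnetization
  float64.
* Voxel convention: half-open boxes, label of a shared face belongs to the
  higher-index voxel; fields evaluated at voxel centers.
* Default desk-scale grid for cylinder phantoms is 256^3.  This is a
  deliberate reduction from the 1000-1200^3 meshes used at full scale; the
  coarser mesh (2.34 um voxels at 600 um FoV, i.e. ~3.4 voxels per 8 um
  radius) is the dominant accuracy limit for small vessels.  In the
  spin-echo radius sweep it flattens the peak region: the measured
  percent-change curve tops out between the 2.6 and 3.4 um grid points with
  the two values within one Monte-Carlo standard error of each other,
  whereas a finer mesh (1.17 um voxels) moves the maximum towards 3.4-4 um.
  The sweep argmax at desk scale is therefore resolved only to about one
  grid step (factor 1.27).
* Shipped experiment sizes: leakage experiment 5e4 spins x 2e4 steps
  (~4 min); radius sweep one 256^3 phantom, 15 radii x 2 states x 1e4 spins
  x 600 steps (~3 min including phantom generation); bSSFP steady-state
  check 8 spins x 2.2e5 steps (~10 s).

## Known limitations

* Desk-scale meshes bias small-vessel results (above); use finer grids when
  accuracy near 1 um vessels matters.
* No flow, no spin replenishment: long permeable simulations (bSSFP-length)
  progressively drain compartments, which is faithful to the scheme but not
  to physiology.
* Per-spin RNG streams are not stable under a change of spin count (one
  generator per run); only full-run reproducibility is guaranteed.
* Gradients are sampled on the dt grid as instantaneous values; no intra-step
  waveform integration.
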