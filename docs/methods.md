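# Methods

This note documents the models, numerical choices, and known limitations
behind `porocell`. Units throughout: lengths in um, time in s, pressures
and moduli in kPa (so permeability `k = D/M` carries um^2/(kPa s)).

## Physical model

A cell is treated as a fluid-saturated poroelastic body: a drained
elastic skeleton (cytoskeleton, organelles, macromolecules) permeated by
cytosol. Osmotic and hydrostatic imbalances across the membrane are
lumped into one *effective pressure* `P_eff = (p_o - p_i) - (Pi_o - Pi_i)`;
positive values drive fluid in (swelling), negative out (deswelling).
The boundary forcing rises linearly over a finite *rise time* `t_r`,
modeling both the finite speed of any real medium exchange and the
time-dependent barrier behavior of the membrane; `t_r = 0` is a step.

Constitutive assumptions (linear regime): isotropic drained elasticity
`(E, nu)` with Biot coefficient 1 and incompressible constituents — the
soft, fully saturated limit — so total stress is `sigma = sigma'(u) - p I`
and fluid content change equals dilatation. Darcy flow `q = -k grad p`
with `k = D / M`, `M = 2G(1-nu)/(1-2nu)` the oedometric modulus, makes
the 1D reduction a pure diffusion equation for the pore pressure with
coefficient `D` (the poroelastic diffusion constant), tying the
relaxation timescale to `t_p ~ H^2 / D`.

### 1D closed forms (`porocell.analytic`)

For a laterally confined layer of thickness `H` on an impermeable
substrate, drained from the top where the pressure steps to `P_eff`:

* plateau: `delta_inf = P_eff H / M` (sign follows `P_eff`);
* transient: `delta(t)/delta_inf = 1 - sum_{n odd} (8/n^2 pi^2)
  exp(-n^2 pi^2 tau)` with `tau = D t / (4 H^2)`;
* early time (half-space): `delta/delta_inf = (2/H) sqrt(D t / pi)`,
  accurate to <0.5% for `tau <= 0.01`;
* pore-pressure / chemical-potential profile: odd-harmonic sine series
  (finite layer) or `erf(-z / sqrt(4 D t))` (half space). The erf form is
  used because it satisfies both boundary conditions (0 at the drained
  surface, 1 in the undisturbed interior) and matches the finite series
  to <1% in its stated validity range; an erfc variant circulating in the
  literature does not meet the boundary value.

Two dimensionless times exist side by side on purpose: the consolidation
time `D t/(4H^2)` in the series and the figure-normalization time
`4 D t/(pi H^2)` used for curve overlays; their ratio is exactly `16/pi`
and they are exposed as distinct functions, never interchanged.

The ramp response is the convolution of the step response with the
normalized loading rate. Because every series term is an exponential,
the convolution integrates in closed form (per-term `(1 - e^{-l t})/l`
factors), so no quadrature is involved; the tests verify agreement with
a brute-force trapezoid convolution to well under 0.1%. Series
truncation is adaptive with an absolute tail bound of 1e-12 and a floor
of 100 odd terms, capped at n = 200001 (for `tau < ~1e-12` the truncated
tail can reach ~2e-6 in absolute value, far below any quantity of
interest here); `tau = 0` is returned exactly.

## Transient solvers (`porocell.solver`)

No finite-element library is part of the runtime stack, so the package
carries a small, fully vectorized axisymmetric FEM of its own:
8-node serendipity quadrilaterals for displacement and bilinear corner
pressures (a quadratic/linear mixed pairing that is inf-sup stable for
consolidation problems), 3x3 Gauss quadrature, structured meshes mapped
onto the three geometries:

* `disk` — cylinder `H = 5.5`, `R = 15` (idealized adherent cell);
* `cell_cap` — elliptical cap `z(r) = H sqrt(1-(r/R)^2)`; the contact
  line is truncated at a 0.35 um rim height with radial grading toward
  the rim so elements stay well shaped. Surface probes default to
  heights 5.5/4/2.5 um (P1 apex, P2, P3);
* `column1d` — laterally confined column drained only through the top:
  the exact setting of the 1D series, used as the solver's oracle.

Boundary conditions: the substrate is always impermeable, with `no_slip`
(u = 0) or `free_slip` (u_z = 0) mechanics. Drained surfaces carry the
prescribed boundary pore pressure `P_eff(t)` and are traction-free by
default (`drained_traction="none"`), which is the standard osmotic
boundary condition and reproduces the 1D analytics exactly on the
column. The alternative `match_pressure` realization additionally
applies an outward normal surface tension equal to `P_eff(t)` on drained
surfaces (follower load in the finite-strain solver); see "Published
reference values" below for why this option exists.

Time integration is backward Euler with geometric step growth (default
1.3x per accepted step, capped at 2x and at `max_dt`), the initial step
`t_r/20` (0.01 s for steps), and a forced step landing on `t = t_r`.
The linear path assembles constant `K`, coupling and permeability
matrices once and refactorizes only when `dt` changes. The
finite-strain path (`solve_porohyperelastic`) uses a compressible
neo-Hookean split `sigma' = (2 C10/J) dev(b_bar) + (2/D1)(J-1) I` with
`C10 = G/2`, `D1 = 2/K_bulk` derived from `(E, nu)` so the small-strain
limit recovers linear elasticity exactly (asserted by test at <2% for
~0.4% strains); kinematics are total-Lagrangian with balance laws
evaluated on the deformed configuration, mass balance
`dJ/dt = Div(J F^{-1} q)` with spatially isotropic constant `k`
(deformation-dependent permeability is not modeled). Newton iterations
use a finite-difference consistent tangent assembled element-wise in one
vectorized batch (all 20 local dof perturbations at once, eps = 1e-6);
non-convergence or element inversion triggers dt halving. The residual
tolerance is scaled by `max(|P_eff|, 1e-3 E) * R * H` so the zero-load
case does not chase round-off.

Verification: the column reproduces the 1D series to <1% sup-norm for
steps and <1.5% for ramps (time-discretization error dominates; both
bounds hold at ~200-400 steps); fluid mass balance — dilatation-based
volume change vs line-quadrature Darcy influx through the boundary —
closes to 1% on a refined column (the influx estimator is first-order in
mesh size because the bilinear pressure gradient is one-sided at the
boundary; the test also asserts the expected convergence rate); mesh
convergence of the disk plateau reaches <0.1% change within three
uniform refinements. Default meshes (disk 24x10, cap 20x8, column 2x24)
were fixed by these convergence studies; the headline runs use 240-960
elements and complete in seconds to tens of seconds on one core.

### Published reference values and the boundary-condition ambiguity

Two headline checks intentionally fail, and one succeeds only when the
drained boundary is also loaded mechanically:

* The published FE disk swelling plateau (~0.4 um at E = 1 kPa,
  nu = 0.3, P_eff = 0.05 kPa, H = 5.5 um) is twice the 1D closed form
  `P_eff H / M = 0.204 um` for identical parameters — the same closed
  form the original analysis itself derives. Under the traction-free
  drained condition this solver yields 0.19 um on the disk (the small
  reduction from 0.204 is real 2D drainage/constraint geometry). With
  `match_pressure` the confined column equilibrates at effective stress
  `2 P_eff` (verified exactly by test) and the disk gives 0.38 um,
  matching the published value — strong evidence the original runs
  imposed the effective pressure both as boundary pore pressure and as a
  mechanical surface load. The package default remains traction-free
  (the physically standard osmotic condition); the acceptance runs use
  it and report the discrepancy rather than switching realizations per
  quantity, because the same `match_pressure` choice overshoots the
  published cell-cap plateau by ~2x when the hyperelastic constants are
  derived from (E = 1 kPa, nu = 0.3).
* A linear poroelastic model is exactly mirror-symmetric in the load
  sign, so its deswelling plateau time equals its swelling one (5.0 s at
  the 98% criterion here); the published asymmetry (~4 s vs ~3.5 s) is a
  large-displacement effect outside the linear setting those values are
  checked in. The finite-strain solver does break the symmetry in the
  expected direction (deswelling faster), as a test demonstrates on the
  cap.
* The published cap plateau time ~11 s belongs to the slowest studied
  ramp (`t_r = 10 s`; the fast-ramp cap plateaus near 5.6 s), so the
  corresponding acceptance quantity is computed from the `t_r = 10 s`
  run (12.5 s here), while the plateau displacement itself — rise-time
  independent, verified to 1% across `t_r` — is taken from the
  `t_r = 1 s` run.

The 98% plateau fraction used for all `t_inf` values is itself a
convention (the published criterion is not stated); it was chosen so the
1D analytic step gives ~4.5 s at D = 10, H = 5.5.

## Bead z-tracking (`porocell.imaging`)

A membrane-attached 500 nm fluorescent bead imaged out of focus casts a
central blob plus concentric rings; the outer ring radius grows linearly
with defocus distance, so z is read off a per-bead linear calibration.
Pipeline per frame:

1. **Centroid**: 2D Gaussian + constant fitted on a circular window
   (default radius 10 px, ~4x the blob extent) around the seed, with a
   robust `soft_l1` loss so ring-tail pixels act as outliers; a
   high-frequency noise estimate (median neighbor difference) rejects
   flat frames. Sub-pixel accuracy ~0.1 px on default-noise frames.
2. **Radial projection**: annulus-averaged intensity with triangular
   sub-pixel weights (each pixel's intensity split linearly between the
   two neighboring annuli, interval 1 px by default). The projection
   conserves total weighted intensity to 1e-9 and matches a per-pixel
   double-loop oracle to 1e-10.
3. **Outer ring**: the profile is normalized to its maximum and the
   *outermost* downward 5% crossing located by linear interpolation.
   Annuli extending beyond the frame (accumulated weight well below the
   full-circle value `2 pi r`) are excluded — their means come from a
   handful of corner pixels. An inner exclusion radius is available when
   inner structures dip below threshold.
4. **Calibration**: ordinary least squares `z = slope * radius +
   intercept` over a 100 nm-step stage scan (>= 3 pairs required);
   extrapolation beyond the scanned radius range is refused by default.
   The 5%-crossing estimator carries a roughly constant offset relative
   to the geometric ring radius; because calibration and tracking use
   the same estimator, the offset cancels in the slope and in all
   relative displacements (it surfaces only as an intercept shift).
5. **Trajectory**: frames processed in timestamp order; failures are
   flagged and excluded, never interpolated; >20% failures marks the
   track unreliable. `delta(t) = z(t) - z(first good frame)`.

On synthetic series at the default noise model the end-to-end RMS z
error is ~2 nm over a 1 um excursion, comfortably inside the ~10 nm
resolution claimed for the technique.

**Volume from confocal stacks**: border-median background subtraction,
Gaussian smoothing (sigma 1 voxel), Otsu threshold (rejected as
"no foreground" if it falls within 4x the border noise), then
morphological opening and closing with a 1-voxel cross; erosions treat
out-of-bounds as foreground because an adherent cell is truncated by the
coverslip plane at the stack border, not surrounded by background there.
Volume = nonzero voxels x voxel volume. Accuracy ~0.2% on noiseless
ellipsoids and ~1% absolute on noisy cap stacks; volume *ratios* (the
quantity used experimentally) recover to +-0.5%.

## Synthetic data (`porocell.synthdata`)

All generators are pure functions of (spec, seed) — regeneration is
bit-identical — and return ground truth beside the data. Defaults mirror
the measurement conditions the package targets:

* displacement curves: analytic ramp forward model at the bead height
  times a geometry factor, 100 ms sampling, additive Gaussian noise of
  10 nm (the tracking resolution);
* defocused frames: central Gaussian blob (amp 400, sigma 2 px) plus an
  annular Gaussian ring (width 2 px) whose radius follows the linear
  calibration law (default 0.05 um/px); ring amplitude decays as
  `1/sqrt(radius)` (peak 1000 counts at the reference radius), keeping
  the crest brighter than the blob across the working range; Poisson
  photon noise, 5-count Gaussian read noise, 20-count baseline. This is
  an empirical stand-in for the diffraction pattern — the pipeline's
  contract is only the linear radius-z law, not ring physics;
* calibration scans: 100 nm z-steps (default 12 frames from z = 1.1 um);
* confocal stacks: half-ellipsoid (or full ellipsoid) cells, 40 slices
  at 0.2 um, interior intensity scaled by the inverse volume ratio
  (fluorophore concentration rises as water leaves), Gaussian background
  noise.

What passing on these fixtures does *not* show: robustness to stage
drift, photobleaching, overlapping beads, non-elliptical cells, or
active regulatory volume dynamics — none of which the generators
emulate.

## Inverse fitting (`porocell.fitting`)

Given a measured curve and the bead height `H`, with `nu = 0.3` fixed
and `E` fixed per direction (0.975 kPa swelling / 1.15 kPa deswelling,
from indentation averages), the fit recovers `(P_eff, D, t_r)` on the
first 40 s (beyond which cytoskeletal remodeling violates the purely
poroelastic assumption):

* stage 1 fits `(P_eff, D)` at `t_r = 0`: a 25-point log-spaced coarse
  grid in D within [0.1, 50] um^2/s followed by bounded 1D refinement;
  `P_eff` is obtained in closed form at each D (the model is linear in
  the load) and clipped to [0.01, 5] kPa;
* stage 2 scans `t_r` in 0.1 s increments up to 10 s, re-optimizing D
  locally (warm-started) at each candidate; the global RMS minimum wins
  and ties go to the smallest `t_r` (parsimony). The objective is the
  RMS of model minus data on the data's own grid.

The default forward model is the analytic 1D ramp response at the bead
height scaled by a geometry factor — the cap-solver/1D plateau ratio at
the probe's relative height (0.95 at the apex down to 0.72 at 2.5 um,
frozen from a linear cell-cap solve and regenerable via
`calibrate_geometry_factor`). The factor only rescales the recovered
`P_eff`; `D` and `t_r` are set by the curve's shape. The surrogate's
transient shape differs slightly from the full cap solution (lateral
drainage), which is the main systematic of the fast mode; `solver_disk`
and `solver_cell_cap` forward modes run the transient solver per
candidate for exact (much slower) fitting. Self-consistency: noise-free
synthetic curves recover parameters to <0.1%; at 10 nm noise, D recovers
within ~4% and `t_r` within one grid step over 20 seeds. A property
test documents that windows shorter than ~2 `t_p = H^2/D` degrade D
recovery — rise time and pore-pressure diffusion act on the same
timescale, the identifiability limit inherent to the method.

Batch fitting aggregates per-direction means and sample SDs; curves with
no clear direction (late-time mean within 3x the point-noise scale) are
flagged and excluded.

## Limitations

* Isotropic, time-constant poroelastic parameters; no solid-phase
  viscoelasticity, no nucleus, no membrane mechanics beyond the
  effective rise time, no active ion transport.
* Structured meshes only; the cap's contact line is truncated at a small
  rim height rather than resolved.
* The hyperelastic solver supports single-layer materials; the two-layer
  (membrane) variant is linear-only.
* Boundary Darcy flux for the conservation check is a first-order
  estimator (see above); reaction-based fluxes would be exact but would
  make the check circular.
* The fit fixes (E, nu) and a template geometry; per-cell geometry is
  absorbed into the bead height and geometry factor.
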