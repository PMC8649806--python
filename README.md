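# porocell

Poroelastic analysis of osmotically driven cell volume dynamics.

When the osmolarity around an adherent cell changes, water flows across
the membrane and the cell swells or shrinks. Treating the cell as a
fluid-saturated poroelastic body — an elastic cytoskeletal sponge
permeated by cytosol — the *rate* of those volume changes is set by how
fast pressure equilibrates through the network: the poroelastic
diffusion constant `D` fixes the relaxation timescale `t_p ~ H^2/D` of a
layer of thickness `H`, the drained moduli `(E, nu)` fix the amplitude
`delta_inf = P_eff H / M` with `M = 2G(1-nu)/(1-2nu)`, and the lumped
effective pressure `P_eff = (p_o - p_i) - (Pi_o - Pi_i)` drives the
flow, ramping up over a finite rise time `t_r` rather than as an ideal
step.

`porocell` is for biophysicists who measure such transients (typically
by tracking membrane-attached beads with defocusing microscopy) and want
to model them quantitatively. It provides:

* **`porocell.analytic`** — closed-form 1D consolidation solutions:
  step and finite-rise-ramp responses, plateau, early-time self-similar
  law, pore-potential profiles, and the two standard dimensionless
  times.
* **`porocell.solver`** — transient axisymmetric finite-element solvers
  for linear Biot poroelasticity and neo-Hookean porohyperelasticity
  (large strain), on disk, elliptical-cap-cell, and confined-column
  geometries, with ramped effective-pressure boundary conditions,
  probe displacement traces, full field snapshots, curve-collapse and
  mesh-convergence utilities.
* **`porocell.imaging`** — the defocused-bead z-tracker (sub-pixel
  Gaussian centroid, triangular-weighted radial projection, 5%-crossing
  outer-ring detection, linear radius-z calibration; ~2 nm RMS on
  synthetic data) and confocal voxel-counting cell volume.
* **`porocell.fitting`** — the staged inverse fit recovering
  `(P_eff, D, t_r)` from a displacement curve with `(E, nu)` fixed.
* **`porocell.synthdata`** — seeded generators for every input the
  pipeline consumes, with ground truth attached.
* **`porocell` CLI** — `simulate`, `analytic`, `track`, `calibrate`,
  `volume`, `fit`, `make-fixtures`, `reproduce-figures`.

## Worked example

Simulate constrained swelling of the cell-like elliptical cap (apex
height 5.5 um, radius 15 um; E = 1 kPa, nu = 0.3, D = 10 um^2/s) under a
0.5 kPa effective-pressure ramp with a 1 s rise time, then locate the
plateau time:

```python
from porocell.materials import PoroelasticMaterial, RampLoad
from porocell.solver import (BoundaryConditionSet, GeometrySpec,
                             SolverConfig, solve_porohyperelastic,
                             time_to_plateau)

mat  = PoroelasticMaterial(E=1.0, nu=0.3, D=10.0)
geom = GeometrySpec(kind="cell_cap", H=5.5, R=15.0)
bcs  = BoundaryConditionSet(bottom_mech="no_slip", drained_traction="none")
cfg  = SolverConfig(end_time=40.0, dt_init=0.02, growth=1.2, max_dt=0.5,
                    nx=16, nz=6)

res = solve_porohyperelastic(geom, mat, bcs, RampLoad(P_eff=0.5, t_r=1.0), cfg)
apex = res.probe("P1")
print(f"apex plateau {apex.delta[-1]:.3f} um, "
      f"t98 {time_to_plateau(apex, 0.98):.2f} s")
```

```
apex plateau 1.993 um, t98 5.76 s
```

The apex rises by about 2 um (36% strain — well into the finite-strain
regime, which is why the neo-Hookean solver is used) and reaches 98% of
its plateau in ~6 s: the relaxation outlives the 1 s ramp because
pressure must diffuse through the full cell thickness. Rerunning with
`t_r` anywhere from 0.1 to 10 s changes the transient shape but the
plateau stays within 1% — the drained equilibrium does not remember the
loading rate.

The same workflow from the shell, for the fast-recalibration fit of a
measured (here synthetic) bead curve:

```bash
porocell make-fixtures --out fixtures --seed 3
porocell fit --curve fixtures/curve_swelling_a.csv --height 2.9 --out fit_out
```

```
swelling: P_eff +0.600 kPa, D 1.989 um^2/s, t_r 4.5 s
wrote fit_out/fit_results.csv
```

The fixture was generated with `P_eff = 0.6 kPa`, `D = 2 um^2/s`,
`t_r = 4.5 s` plus 10 nm tracking noise; the staged fit recovers all
three (pressure and diffusion constant within a percent, rise time to
the 0.1 s grid it scans on).

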