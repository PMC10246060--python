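# tmsfield

A toolkit for modelling the electric fields induced by transcranial magnetic
stimulation (TMS), aimed at the computational core of real-time
neuronavigation: given a figure-8 coil pose on a head model, produce the
induced E-field — either by solving the quasi-static volume-conductor problem
(the slow, trustworthy route) or through a trained convolutional surrogate
(the sub-second route a clinician-facing tool needs), and stream the result
over an OpenIGTLink-subset wire protocol to a viewer.

It is written for researchers and engineers building or validating TMS
planning pipelines: everything runs on synthetic multi-shell spherical heads
generated in-package, on one CPU core, with seeded determinism end to end.

## The model

Under the quasi-static approximation the induced field is

    E = −∂A/∂t − ∇φ,        ∇·(σ (∇φ + ∂A/∂t)) = 0,

with zero normal total current on the head surface. The primary term ∂A/∂t
comes from the coil winding in closed form (straight-segment discretization
of two counter-wound loops); the secondary term solves the
current-conservation equation on a per-voxel conductivity-tensor volume σ via
a conservative finite-volume scheme (distance-weighted harmonic face
conductivities, cut-cell surface weighting, preconditioned Krylov solve).

The surrogate is a multi-scale 3D residual U-Net mapping the 9-channel
reduced field of view (6 tensor + 3 ∂A/∂t components) to the 3-component
E-field, trained with deep supervision at three scales and scored by the
normalized RMS error

    NE = sqrt( Σ‖E_pred − E_true‖² / Σ‖E_true‖² )

over the head mask (0 = perfect, 1 = the zero predictor). The network engine
is a self-contained numpy implementation (im2col convolutions with explicit
backward passes), so the whole package has no deep-learning framework
dependency.

## Worked example

```python
import numpy as np
from tmsfield import headmodel, coilmodel, fieldsolver

cv, geom = headmodel.make_sphere_head()          # 5-shell sphere, 48^3 at 2.5 mm
coil = coilmodel.make_figure8_coil()             # 70 mm-class figure-8, dI/dt = 1 A/us
pose = coilmodel.pose_at_site(geom, np.array([0.0, 0.4, 0.92]),
                              handle_angle_deg=45.0)

dadt = coilmodel.dadt_field(coil, pose, cv.tensors)
pot = fieldsolver.solve_potential_fdm(cv, dadt, tol=1e-8)
E = fieldsolver.total_efield(dadt, pot)

inside = cv.mask.values > 0
print(f"solved {inside.sum()} voxels in {pot.n_iter} CG iterations "
      f"(residual {pot.residual:.1e})")
print(f"peak |E| in the head: {np.linalg.norm(E.values, axis=-1)[inside].max():.3f} V/m")

sample = fieldsolver.ground_truth_case(geom, cv, coil, pose, fov_shape=(24, 24, 24))
print(f"training case: input {sample.input.shape}, target {sample.target.shape}")
```

prints

```
solved 47048 voxels in 245 CG iterations (residual 9.8e-09)
peak |E| in the head: 0.675 V/m
training case: input (24, 24, 24, 9), target (24, 24, 24, 3)
```

0.675 V/m is the peak field in the scalp under the coil at dI/dt = 1 A/μs;
fields scale linearly with dI/dt (a clinical pulse is of order 100 A/μs). The
training case is the (conductivity, ∂A/∂t) → E triple on the 24³ reduced
field of view centered at the coil's scalp projection — the unit the
surrogate trains on (`surrogate.train_surrogate`) and the serving loop
predicts from (`streaming.run_server_loop`).

## Command line

`tmsfield` exposes the pipeline as subcommands — `make-head`,
`sample-placements`, `dadt`, `solve`, `make-dataset`, `train`, `predict`,
`serve`, `client-demo`, `benchmark`, `reproduce-table2`, and an end-to-end
`demo` — all driven by a YAML config (`--config`), a seed override (`--seed`)
and an artifact directory (`--out`). For example:

```bash
tmsfield reproduce-table2 --out out/
```

recomputes the packaged benchmark comparison (10 subjects × 2 CPU machines;
a FEM-based visualizer vs. the real-time predictor route) and prints

```
benchmark comparison (packaged fixture, 10 subjects x 2 machines)
  simnibs_mean_s = 7.58798
  ...
  => pooled t(38) = 56.3, p = 3.24e-38; mean speed-up (printed column) 78.83x
```

## Layout

| module | contents |
| --- | --- |
| `tmsfield.geometry` | voxel grids, rigid transforms that rotate stored vectors, resampling/projection, NIfTI/STL/PLY/TRK I/O |
| `tmsfield.headmodel` | synthetic multi-shell spherical heads, white-matter anisotropy, synthetic fiber bundles |
| `tmsfield.coilmodel` | figure-8 winding, closed-form ∂A/∂t, EEG 10–10 placement sampling |
| `tmsfield.fieldsolver` | finite-volume quasi-static solver, E-field assembly, training-case generation (HDF5) |
| `tmsfield.surrogate` | numpy 3D Res-UNet, training loop, NE metric, checkpointing |
| `tmsfield.streaming` | OpenIGTLink-subset codec (TRANSFORM/IMAGE, CRC-64), loopback/TCP transports, serving loop |
| `tmsfield.evaluation` | timing summaries, pooled t-test, packaged benchmark fixture |
| `tmsfield.app` | YAML config + `tmsfield` CLI |

`docs/methods.md` documents the model, the discretization, the network, the
synthetic-data generator's scope, and the numerical design choices.
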