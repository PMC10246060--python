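# Methods

`tmsfield` models the physics behind real-time transcranial magnetic
stimulation (TMS) planning: a figure-8 coil drives a rapidly changing current,
the changing magnetic vector potential induces an electric field in the head,
and a clinician wants that field — for an arbitrary coil position and
orientation — in well under a second. The toolkit implements the slow,
trustworthy route (a quasi-static volume-conductor solve) and the fast route
(a convolutional surrogate trained on solved cases), together with the
geometry, streaming and evaluation machinery that connects them.

## Quasi-static field model

Under the quasi-static approximation the induced field splits into a primary
and a secondary part,

    E = −∂A/∂t − ∇φ,        ∇·(σ (∇φ + ∂A/∂t)) = 0,

with zero normal total current σ(∇φ + ∂A/∂t)·n = 0 on the head surface.
σ is the per-voxel symmetric 3×3 conductivity tensor (S/m). φ is determined
up to a constant; we fix the zero-mean gauge over the head mask. Two
consequences of this model are used as validation oracles throughout:

- E is invariant under global scaling σ → cσ (the equation is homogeneous
  in σ), and linear in the coil current rate dI/dt;
- in any spherically symmetric conductor the induced E has no radial
  component, and for a circular loop coaxial with the sphere φ vanishes
  identically (azimuthal symmetry).

### Coil model and primary field

The figure-8 coil is two coplanar counter-wound circular loops (default:
27 mm radius, centers ±27 mm, a 70 mm-class treatment-coil geometry),
each discretized into straight segments (default 64 per loop). For a straight
segment the line integral of 1/|r−r′| has a closed form, so

    ∂A/∂t(r) = (μ0 dI/dt / 4π) Σ_seg l̂ · ln((ra+rb+L)/(ra+rb−L)),

evaluated at every voxel center, in the world frame. Chord endpoints are
placed on a slightly enlarged radius so the polygon's enclosed area equals the
circle's; this cancels the leading discretization error and brings the
64-chord field within ~2·10⁻⁷ relative L2 of a 10×-refined reference (a naive
inscribed polygon sits near 10⁻³). Points closer than 0.5 mm to a wire are
clamped to that guard distance with a logged warning; with a 2 mm scalp
standoff this only affects voxels outside the head directly under the coil
junction. Default dI/dt is 1 A/μs; fields scale linearly for any other value.

### Finite-volume solver

The potential equation is discretized cell-centered on the voxel mask:

- two-point fluxes per face; the diagonal face conductivity is a
  distance-weighted harmonic mean, with the interface position placed
  sub-voxel from generator-provided signed distances when available;
- the face source term is the flux-matched form σ_harm · mean(∂A/∂t) — not
  the mean of σ∂A/∂t, which at a 165× skull/CSF jump produces spurious
  interface sources (flux matching across the interface derives the harmonic
  weighting for the source exactly as for the potential flux);
- tensor cross terms (white-matter anisotropy) enter through face-averaged
  central differences, dropped where the stencil leaves the mask;
- faces on the mask boundary carry no terms at all: this is the natural weak
  form of the zero-total-current condition. (The sanity check that pins the
  sign conventions: a uniform ∂A/∂t along an insulated homogeneous bar must
  produce E ≡ 0; an explicit boundary source term fails it.)
- faces near the outer surface are scaled by the wetted-area fraction
  estimated from the signed distance (a first-order cut-cell treatment).

The assembled system is symmetric positive semi-definite for diagonal
tensors and is solved with Jacobi-preconditioned conjugate gradients; tensor
cross terms make the stencil mildly nonsymmetric, and the solver switches to
BiCGSTAB with an incomplete-LU preconditioner. Relative residual tolerance
1e-8 (configurable); the singular pure-Neumann system is handled by
projecting the (discretely tiny) net source out of the right-hand side and
applying the zero-mean gauge afterwards. Non-convergence raises an error
carrying the final residual.

E is recovered with central differences inside the mask and one-sided
differences at its boundary, in V/m (grid spacing converted from mm).

### Accuracy and the staircase skin

The voxelized sphere has a staircase surface, and tissue interfaces cut voxel
faces obliquely. Cell-centered gradients within 1–2 voxels of these surfaces
carry O(10%) radial artifacts that do not shrink in max norm with refinement —
the standard limitation of voxel solvers versus conforming-mesh FEM. The
physics validations are therefore measured over the brain region (r ≤ 0.8 R),
where the field actually matters for TMS dosimetry and where the checks
converge. On the homogeneous 48³ sphere (2.5 mm voxels):

- max radial fraction of E: 1.1–1.8% across coil poses (bound used: 5%),
  decreasing 2.8% → 1.1% → 0.8% over 24³ → 48³ → 64³;
- coaxial-loop max‖∇φ‖ / max‖∂A/∂t‖: 0.28% (bound used: 1%);
- conductivity-scaling and dI/dt-linearity hold to solver tolerance (≲1e-5).

The default 5-shell head (scalp 0.465, skull 0.010, CSF 1.654, gray matter
0.275, white matter 0.126 S/m — standard literature values) shows larger
interface skins; it is the default for surrogate data generation, while the
homogeneous sphere is the canonical configuration for the symmetry-based
solver validations.

## Synthetic heads, placements, and what they do not emulate

`make_sphere_head` builds concentric-shell spheres on an isotropic grid
(default 48³ at 2.5 mm, 56 mm outer radius): each voxel takes the conductivity
of the innermost shell containing its center (a center exactly on a radius
belongs to the outer shell); icosphere meshes are generated at the scalp and
gray-matter radii. `randomize_conductivity_tensors` adds white-matter
anisotropy: per voxel a random principal axis with eigenvalue ratio
λ1/λ⊥ = ratio, trace-preserving, so isotropy (ratio 1) is exactly the
identity. `make_synthetic_streamlines` produces arc-shaped fiber bundles
strictly inside the white-matter core for projection/display testing.

Coil placements sample an idealized EEG 10–10 layout: 73 labelled unit
directions built programmatically (nine ear-to-ear arcs at 18° midline steps
with equal within-arc spacing, plus a 12-site lower ring 18° below the ear
plane). It is a geometric idealization, not a measured montage; labels are
nominal. At each site the coil normal points at the head center with a 2 mm
scalp standoff; the handle angle steps evenly over 360° (reference direction:
the local tangent toward the nasion); the default study draw is 300 of the
73×78 enumerable (site, direction) pairs, seeded.

Passing tests on these heads show the pipeline is internally consistent
(correct equations, conservative discretization, learnable mapping). They say
nothing about segmentation error, realistic cortical folding, skull
inhomogeneity, or diffusion-tensor estimation — real-head accuracy must be
established against real head models.

## The surrogate

A residual encoder–decoder maps the 9-channel reduced field of view (6 tensor
components, then 3 ∂A/∂t components) to the 3-component E-field. The 3×3×3
convolutional trunk runs at half resolution and below (a stride-2 stem):
encoder stages halve resolution and double channels with residual blocks;
decoder stages upsample (nearest), merge the skip connection, and apply a
residual block. A pointwise full-resolution stage refines upsampled features
concatenated with the raw input (the full-resolution skip). Deep supervision:
1×1×1 heads predict the field at every scale, and the loss is the weighted
sum of per-scale vector MSEs against average-pooled targets, weights
(1.0, 0.5, 0.25) fine→coarse. The stride-2 stem is what makes CPU training
practical — the engine is a hand-written numpy im2col/GEMM implementation
with explicit backward passes — at the cost of fine-grained full-resolution
features the pointwise stage cannot fully recover.

Defaults: 3 levels, base 8 channels, batch 4, Adam with linear warmup over
the first 5% of steps then cosine decay from 2e-3, 100 epochs. Inputs are
z-scored per channel; targets divided by their global RMS; both statistics are
stored in the checkpoint (a single `.npz` with weights, config, statistics
and per-epoch history). Everything is float32 and bitwise-reproducible from
the config seed (weight init and batch shuffling).

Quality metric:

    NE = sqrt( Σ_mask ‖E_pred − E_true‖² / Σ_mask ‖E_true‖² )

over the head mask of each case — 0 for perfection, exactly 1 for the zero
predictor, and 1 for a 2× overprediction (the metric is a normalized residual,
not a correlation). The vector field is the learning target; the magnitude
image streamed to a viewer is derived per voxel afterwards.

The toy corpus used by the acceptance checks is 80 solved placements (64
train, 16 held out) on a 40³/2.5 mm five-shell head with a 24³ FOV centered at
each coil's scalp projection. Held-out NE after 100 epochs is ≈0.6–0.7 —
clearly below the zero-predictor baseline of 1.0 and far below the untrained
network, which is what these desk-scale conditions can demonstrate. Pushing
toward the ≈0.2 NE regime reported for full-scale anatomical pipelines
requires real head models, far more cases, and GPU-scale training, all out of
scope here.

## Streaming protocol

Messages use the OpenIGTLink v2 58-byte big-endian header (version 2,
12-byte type name, 20-byte device name, nanosecond timestamp, body size,
CRC-64/ECMA-182 of the body) with two supported types. TRANSFORM carries 12
float32 values (3×3 rotation column-major, then the offset, mm); decoded
rotations are re-orthonormalized via SVD since float32 wire precision erodes
the 1e-9 rigidity gate. IMAGE uses a compact subset body — dims (3×uint16),
spacing (3×float32), dtype code, raw big-endian float32 voxels — not the full
OpenIGTLink IMAGE subheader. The server loop answers each pose with the
predicted magnitude image, timing the prediction (cnn) and encode/transmit
(vis) components separately per run; transports are an in-process loopback
(tests) and blocking TCP (deployment), both ordered and reliable. Malformed
inbound messages are logged and skipped; transport loss aborts the session
with partial statistics attached.

## Evaluation statistics

`two_sample_ttest` is the pooled-variance (Student) independent-samples test,
df = n1+n2−2, two-sided p from the t distribution — pooled rather than Welch
because the benchmark it reproduces reports df = 38 = n1+n2−2; on those data
both variants agree to three significant figures. Timing summaries use the
sample (n−1) standard deviation over a fixed number of runs (default 50).

The packaged benchmark fixture transcribes published visualization timings
(10 subjects × 2 CPU machines × 2 tools: a FEM-based visualizer, "simnibs",
and a real-time DL predictor, "realtime"). Its printed per-subject mean and
improvement columns contain small internal inconsistencies (a per-subject
mean equal to one machine's cell; improvement factors that are not exactly
the ratio of the printed means); the fixture preserves them verbatim and the
report carries both the as-printed and the recomputed variants. Everything
derived from the fixture is exact arithmetic on printed numbers: pooled means
7.58798 ± 0.59553 s vs 0.08506 ± 0.02365 s, mean printed improvement 78.83×,
pooled t(38) = 56.3, p ≈ 3e-38.

## Numerical and design choices, in brief

- World frame RAS millimetres; 0-based voxel indices; affine maps index to
  world. Vector volumes store world-frame components, so a rigid transform
  resamples the lattice *and* rotates the stored vectors — skipping the
  rotation silently corrupts any vector overlay.
- Interpolation: trilinear for fields, nearest for masks; outside samples are
  zero with zero-padding semantics (boundary samples blend toward zero).
- The reduced FOV (default 24³) is cropped around the coil's radial scalp
  projection, zero-filled with a warning where it leaves the grid; odd shapes
  are zero-padded to the network's stride multiple and cropped back.
- Degenerate inputs: non-rigid matrices are rejected (orthogonality within
  1e-9, det +1); zero-energy truth makes NE undefined and raises; a
  zero-variance t-test with unequal means returns a flagged infinite-t
  result.
- The 10–10 handle-direction convention (even 360° spacing, nasion-tangent
  reference) and the 73-site table are documented package conventions;
  alternative montages can be passed explicitly.
- Problem sizes in tests and the acceptance script (48³ physics grids, 40³
  data-generation head, 80 solved cases, 100 epochs) are the package's
  desk-scale study conditions: large enough for every validated property to
  be measurable, small enough to run routinely on one CPU core.
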