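# Methods

## The reconstruction problem

Linear-array photoacoustic computed tomography (PACT) records, at each
mechanical scan position along the elevation axis, one pressure trace per
transducer element. The raw data form a sinogram `p(r_d, t)` indexed
(time sample, element, scan position). The goal is the initial pressure
distribution `p0(r)` on a 3D voxel grid.

The package implements universal back-projection (UBP): for every voxel
`r`, sum over all detector positions `r_d` the conditioned integrand

    b(t) = 2 p(t) − 2 t ∂p/∂t

evaluated at the voxel's time of arrival `t = τ(r, r_d)`, with a per-voxel
normalization standing in for the solid-angle factor `1/Ω0`. The
coordinate frame is (depth z, lateral x, elevation y), mm and µs
throughout; the array face sits at z = 0 looking into +z, so a volume of
200 × 430 × 200 voxels reads depth × probe width × scan distance.

## Delay models

**Point detector.** `τ = |r − r_d| / v_s` with `v_s = 1.54 mm/µs` by
default (soft tissue). Exact for omnidirectional point-like elements.

**Focal-line virtual point detector.** A cylindrically focused element is
not point-like: the acoustic lens focuses it in elevation onto a point at
`depth = focal_length`, and the line through all elements' foci is the
*focal line*. Signals reach the element predominantly via the path that
crosses the focal line, so the element's focus acts as the effective
receiver:

    τ = (F ± |r − r_focus|) / v_s,

`+` for voxels deeper than the focal plane, `−` for shallower ones, with
`|r − r_focus|` the full 3D distance to the focus (lateral offset
included). At `F = 0` this reduces exactly to the point model. Design
notes:

- The ± branch makes the delay continuous and monotonic along the element
  axis; off-axis, the branch switch at `z = F` is a genuine discontinuity
  of the virtual-detector construction. The continuity and monotonicity
  properties are therefore stated (and tested) on the element axis, where
  they are well defined.
- Shallow points far off-axis can give `F − |r − r_focus| < 0` — outside
  the model's validity region. Reconstruction handles this naturally
  (negative delays sample nothing); the forward simulator mirrors it by
  assigning such (element, absorber) pairs zero signal.
- No acceptance-angle cut or proximity-to-focal-line weighting is applied
  by default; the model is purely geometric.

All delays are computed in double precision. `delay_table` streams the
(voxel × element × position) table in tiles under a configurable memory
budget and refuses requests that cannot fit.

## Signal conditioning

`ubp_term` computes `b(t)` with a second-order central finite difference
(first-order one-sided at the trace ends); `t` is absolute time of flight
`t0 + k/fs`, not the sample index. The scheme annihilates linear traces at
interior samples and is exact on quadratics. Fractional delays are
evaluated by linear interpolation; times outside the recorded window read
as zero. An optional zero-phase Butterworth band-pass is provided for
experimental data but is off by default — the pipeline applies no implicit
filtering.

Plain delay-and-sum (back-projecting raw pressure without the derivative
term) is available via `integrand="das"`; the UBP term is the default.

## Back-projection core and its oracle

`reconstruct` is the vectorized production path: scan lines outermost
(progress reporting per line), elements next, voxels processed in
depth-slabs sized by a memory budget (default 1 GiB). Accumulation is in
float64 regardless of input precision — at full geometry each voxel sums
128 × 400 = 51,200 terms. Slab tiling provably does not alter the
per-voxel summation order, so tiled and untiled runs agree bitwise.

`reconstruct_reference` implements the identical contract as the plainest
possible triple loop with scalar delay/interpolation calls. It exists to
be read and to arbitrate: the test suite and `pact-recon selftest` compare
the two on randomized small problems (random geometry, focal length,
sound speed, both delay models, both weightings, both integrands) and
require agreement within 1e−9 relative; in practice they agree bitwise
because both follow the same summation order.

Weighting:

- `uniform` (default): every (element, position) pair contributes equally;
  the sum is divided by the pair count. Chosen for reproducibility; the
  absolute image scale is not a target quantity.
- `solid_angle`: each term weighted by `cosθ / d²` (θ against the element
  normal, contributions from behind the array clipped to zero),
  renormalized per voxel.

No apodization is applied across the aperture.

## Forward simulator

The simulator generates sinograms with known ground truth so the inverse
can be validated end to end.

- **Spheres** (`radius > 0`): the far-field N-shaped pulse
  `p0 (d − v_s t)/(2d)` on `|d − v_s t| ≤ a`. Closed form, so test
  expectations (leading peak `p0 a/2d`, zero crossing at `d/v_s`, zero
  time-integral) are exact. Near-field corrections are omitted; fixtures
  keep receivers several radii away.
- **Points** (`radius = 0`): a derivative-of-Gaussian pulse centered at
  `t = d/v_s`, peak-normalized to the absorber amplitude (no 1/d decay —
  an idealized calibrated impulse). The default width `σ = 0.25 µs` is
  matched to the coarsest fixture grid: the positive correlation lobe
  spans ±`v_s σ` ≈ 0.39 mm ≈ one voxel at RF 2, so argmax localization is
  grid-limited rather than phase-limited. For finer grids, narrow the
  pulse accordingly (it is a per-call parameter).
- The element's arrival time uses the *same* delay model as the intended
  reconstruction, making forward and inverse exact geometric counterparts.
- Noise is additive white Gaussian only, drawn from a fixed seed;
  identical seeds give bit-identical sinograms.
- Vessel-like targets are chains of overlapping spheres along a polyline
  (`sphere_spacing ≤ tube_radius`).

What the simulator does **not** emulate: transducer frequency response and
directivity (an ideal broadband receiver is assumed; an optional band-pass
exists on the conditioning side), acoustic heterogeneity, attenuation, and
laser fluence structure. Passing tests therefore certify the geometry and
the reconstruction operator, not robustness to real-transducer physics.

## Validation geometries and problem sizes

The full-scale acquisition (128 elements, 2.25 MHz, 86/128 mm pitch,
400 lines at 0.1 mm, RF 5) is the configuration default. Validation runs
use scaled-down versions chosen to keep desk-scale runtimes while
preserving what each check exercises:

- *Oracle equivalence*: 20 randomized instances, ≤ 10³ voxels,
  ≤ 8 elements, ≤ 10 scan lines (the reference loop is O(total products)).
- *Point recovery*: 32 elements, 50 scan lines, RF 2 over a
  30 × 24 × 5 mm grid; focal length 20 mm; five noise-free point absorbers
  at 12–25 mm depth (both sides of the focus), off the voxel lattice. The
  scan step is widened to 0.4 mm so the 50-line scan spans 19.6 mm:
  scaling the line count down while keeping the full setup's 0.1 mm step
  would shrink the elevation aperture to 4.9 mm, and at 12–25 mm depth an
  unfocused aperture that small encodes essentially no elevation
  information (the point-spread profile is flat to ~15% across the grid) —
  the scaled experiment must preserve the aperture-to-depth ratio to test
  localization at all. Recording starts at t0 = −1.5 µs so pulses from
  absorbers near the focal model's validity boundary are captured whole.

## Numerical choices and degenerate inputs

- Grid: `dims = round(extent × rf)` per axis, half away from zero; voxel
  centers at `corner + (index + ½)/rf`; index↔coordinate round-trips are
  exact for in-grid indices. Depth extent defaults to 40 mm (giving the
  200-voxel depth at RF 5); lateral extent defaults to the 86 mm probe
  width and elevation to the 40 mm scan.
- Depth-encoded MIP: projects |p0| (back-projection output is signed);
  argmax ties break toward the shallowest depth; brightness is clipped at
  a configurable intensity percentile (default 99) so sparse bright
  targets render without manual scaling; hue is a direct colormap lookup
  of normalized depth.
- Degenerate cases defined rather than erroring: coincident voxel/element
  (delay 0), out-of-window sample times (0), empty phantom (zero
  sinogram), all-zero sinogram (zero volume), voxel coincident with an
  element under solid-angle weighting (weight 0).
- Errors with diagnostics: non-finite input samples (first offending
  index named), shape mismatches, negative focal length, receiver inside
  an absorber, memory-budget violations.

## Known limitations

- The focal-line model is a geometric virtual-detector approximation; it
  does not weight by proximity of the propagation path to the focal line.
- Uniform weighting reproduces relative image structure, not absolute
  pressure units; `solid_angle` is provided but neither convention claims
  quantitative p0 calibration.
- The reference loop is impractical beyond ~10⁴ voxel–trace products; it
  is an oracle, not a fallback.
- Heterogeneous sound speed, refraction, and frequency-dependent
  attenuation are out of scope.
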