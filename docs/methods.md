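# Methods

This note documents the models, algorithms and conventions behind
voxelflow, the parameters that matter, the synthetic data the tests run on,
and the design decisions taken where more than one choice was defensible.

## Data model and conventions

A `Volume` is a dense raster of 1–3 axes with 1–4 channels and one of three
element formats: `u8`, `u16` or `f32`. Integer formats are interpreted as
normalized intensities: `u8` value x maps to x/255 (65535 for `u16`) when
converted to float, and floats map back with round-half-up and clamping —
the same convention GPU texture units use for UNORM formats. `dims` is
x-first and x is the fastest-varying axis in memory; the backing numpy
array therefore has shape `dims[::-1] + (channels,)` in C order.

Three global conventions hold everywhere and are load-bearing for the
equivalence guarantees below:

- **Clamp-to-edge addressing.** Out-of-range coordinates clamp to the
  nearest edge element, in direct sampling and in every neighborhood
  kernel (`scipy.ndimage` `mode="nearest"`).
- **Solidity is `>= t`.** A voxel is "solid"/foreground when its normalized
  intensity is at least the threshold. The same boundary convention is used
  by `threshold` and by the distance transform's preparation pass, so the
  two nodes compose consistently.
- **Swizzle alphabet** `{r,g,b,a,0,1}`: `0` yields zero, `1` the full-scale
  value of the volume's dtype. Swizzle is a read-time argument, not a
  stored property of the volume; storing it would entangle the data model
  with presentation state.

## Dataflow graph

The graph is a DAG of typed nodes. Connector datatypes (`volume`,
`image2d`, `scalar`, `buffer`) play the role of connector colors: an edge
is only accepted when the datatypes match. Cycles are rejected at connect
time by a reachability search from the destination back to the source — an
O(V+E) check per connect, which is negligible against the cost of any
volume kernel and keeps the acyclicity invariant true at all times rather
than detecting violations at execution.

A parameter change (or reconnection) marks the node and its full downstream
closure dirty; `execute()` evaluates exactly the dirty set, in Kahn
topological order with ties broken by node insertion order so reports are
reproducible. Each node records wall-clock compute time in milliseconds;
timing is informational only and never asserted in tests. A node that fails
(exception, or a required input left unconnected) poisons only its
downstream cone: those nodes are skipped and stay dirty, unrelated
subgraphs still execute. The alternative — aborting the whole run — was
rejected because a prototyping tool should surface one branch's error while
the rest of the pipeline keeps producing output.

## Kernel library

**Euclidean distance transform.** The separable squared-distance algorithm
(Felzenszwalb–Huttenlocher): a preparation pass writes squared distance 0
at solid voxels and a finite sentinel elsewhere, one lower-envelope-of-
parabolas pass per axis computes the exact 1D squared-distance transform in
O(n) per line, and a final pass takes square roots — four passes for a 3D
volume. The sentinel is `sum((dim-1)^2) + 1`, strictly above the squared
volume diagonal, so the all-empty volume yields a well-defined finite field
instead of infinities. The result is exact: tests compare against both an
O(n²) brute-force nearest-solid search and scipy's independent EDT, with
max absolute error ~1e-7 (float residue of the square root only).

**Median filter.** The 14th order statistic of the clamped 3×3×3
neighborhood (27 values). The implementation delegates to
`scipy.ndimage.median_filter`; tests verify exact equality with an explicit
full-sort oracle at every voxel including borders. A sorting-network
formulation is a GPU-performance device, not a semantic one, and is not
replicated.

**Rescale intensity.** `(x - min)/(max - min)` over all elements, computed
in float64 so the extremes land exactly on 0 and 1; a constant volume maps
to all zeros by convention (the degenerate case must produce *something*,
and zero is the least surprising choice).

**Convolution.** Separable, one odd-length 1D kernel per axis, clamp
borders. The Gaussian preset samples `exp(-x²/2σ²)` at integer offsets with
radius `ceil(3σ)` and renormalizes to sum 1, so constant volumes are
preserved exactly.

**Derivatives.** Central differences with clamp borders; `derivative`
returns the gradient's Euclidean norm, `surface_normals` the negated
normalized gradient (zero where the gradient vanishes) — pointing outward
from bright regions, which is what a Lambert term expects when bright
means dense.

**Curvature.** Mean curvature of the implicit isosurfaces,
H = ½·div(∇v/|∇v|), evaluated with central differences on the normalized
gradient field. The ½ makes a sphere of radius r (v = distance from
center) report H ≈ 1/r, the standard mean-curvature normalization in 3D.
Voxels whose gradient magnitude is below 1e-8 report 0 (curvature is
undefined on flat fields). The effective stencil radius is 2.

**Elementwise ops** follow IEEE semantics throughout: division by zero
gives ±inf, 0/0 gives NaN, and these propagate without trapping, so a
downstream node sees the honest numerical outcome.

## Tiled execution

`plan_tiles` splits a volume into axis-aligned cores that partition it
exactly, in raster order, growing the number of chunks greedily on the
axis with the largest core until the worst-case tile (core + 2·halo per
axis) fits the voxel budget. Plans are deterministic.

`run_tiled` extracts each core plus a halo at least as wide as the
kernel's declared radius. The halo is filled from neighboring data and
**clipped** at volume borders rather than edge-padded: clipping means the
kernel's own clamp-to-edge rule acts at exactly the true volume border, so
tiled output equals the untiled run *exactly* — including for nonlinear
multi-stage kernels such as curvature, where edge-padding the raw data is
not equivalent to clamping the intermediate unit-gradient field (this
distinction was caught by the tiled-equivalence test and drove the design).
A halo narrower than the declared radius is rejected up front since
correctness could not be guaranteed.

Global and pass-based operations (rescale, which needs the global min/max;
the EDT, whose 1D envelope pass is non-local along its axis) declare no
radius and are exempt from spatial tiling.

## Renderer

Right-handed perspective camera, rays through pixel centers, trilinear
interpolation with clamp-to-edge, default step 0.5 voxels. Voxel i is
centered at world coordinate i + 0.5.

- *translucent*: per-sample opacity α = clamp(intensity · opacity_scale ·
  step, 0, 1) with grayscale emission equal to the intensity — the simplest
  transfer consistent with a translucent look, and documented as the
  replaceable part of the mode; front-to-back compositing with early exit
  at A ≥ 0.999, final color composited over the background.
- *solid*: the ray stops at the first sample ≥ threshold and shades with a
  headlight Lambert term max(⟨−d, n⟩, ambient) from interpolated surface
  normals.
- *solid_rescaled*: solid after mapping intensities onto [0,1].
- *solid_curvature*: the hit point's mean curvature is mapped through
  tanh(κ·scale) onto a diverging blue–white–red ramp (concave vs convex).
- *edge_step*: binary occupancy, white where the ray crosses the threshold.

Anaglyph stereo renders twice with the eye displaced ∓separation/2 along
the camera's right axis and packs the left eye's Rec. 709 luminance into
red, the right eye's into green and blue (red-left is the common anaglyph
convention).

## Live-coded kernels

Snippets are a restricted arithmetic expression dialect over the current
element `v` and scalar parameters declared in the source with
`param name = default` lines; `^` is the power operator. Available
functions: min, max, abs, clamp, exp, log, sqrt, pow, floor, ceil, sin,
cos, step, smoothstep. The source is parsed into a Python AST and checked
against a strict node whitelist; attribute access, subscripts, strings,
imports and calls to anything but the whitelisted functions are rejected at
compile time with a position-carrying diagnostic, and a failed compilation
never yields a partial kernel. Parameters may shadow function names (the
canonical contrast kernel names a parameter `exp`); a shadowed function is
then not callable inside that snippet. Undeclared free variables are a
compile error rather than auto-induced parameters — silent induction would
turn typos into parameters.

A second snippet flavor generates 2D images from pixel coordinates
(`x, y, width, height`), the shader-toy-style generator node.

## File format and plugins

The native format is a 40-byte little-endian header (magic, version,
header size, axis count, channels, dtype code, extents, compressed and raw
payload lengths) followed by the element array compressed with ZStandard
level 3. The explicit header-size field lets future writers append fields
that older readers skip. Readers validate every metadata field and the
decompressed length, and report corrupt magic, future versions, truncation
and garbled payloads with specific errors rather than crashing.

Format plugins are self-contained (name, extensions, content probe,
reader, optional writer). Detection probes content first — the native
format always first — and falls back to extensions; content beats
extension so a mislabeled file still loads correctly. The two bundled
plugins delegate to established readers (nibabel/pydicom/tifffile for
NIfTI/DICOM/TIFF; imageio for PNG/BMP/TGA) rather than reimplementing
those formats.

## Synthetic phantoms and what the tests show

Real clinical volumes cannot be redistributed, so all pipelines run on
procedural phantoms. The sphere phantom is a two-level ball with optional
Gaussian noise, clamped to [0,1]. The head phantom is three nested
ellipsoids — skull/skin shell at intensity 0.9, a thin CSF layer at 0.45,
a brain core at 0.2 carrying a smooth ±0.03 texture — over background 0,
paired with a ground-truth label volume. Class intensity ranges are
disjoint at zero noise by construction, which is what makes exact recovery
by the shipped segmentation graph a meaningful end-to-end correctness
check: the pipeline (rescale → band extraction → Gaussian smooth →
threshold mask gating the skull class → label assembly from thresholds and
elementwise arithmetic) must get every one of 64³ voxels right, and does.
Default phantom size is 64³, which keeps the full suite and the acceptance
script inside seconds on one CPU while leaving every code path exercised.

What the phantoms do *not* emulate: partial-volume effects, bias fields,
anisotropic voxel spacing, Rician MRI noise, or anatomical shape
variability. Passing tests therefore demonstrate algorithmic correctness
of the machinery, not clinical segmentation quality; on real data the
fixed thresholds of the example graph would need tuning, which is exactly
the interactive workflow the graph engine is built for.

## Numerical choices

- EDT computations run in float64 internally; output is f32.
- Rescale extremes are exact (0 and 1) because the affine map is applied
  in float64 and the extreme elements map to 0/(hi−lo)·… symbolically.
- Curvature flat-tolerance 1e-8 on the gradient magnitude.
- Translucent early-exit threshold 0.999 accumulated alpha.
- Tiling tie-break: when several axes share the largest core, the
  lowest axis index is split first; raster (x-fastest) tile order.
- Topological ties break by node insertion order.
- Round-half-up (`floor(x·scale + 0.5)`) for float→integer conversion.

## Known limitations

- The EDT's envelope pass is a per-line Python loop; fine for the
  test-scale volumes this repo targets, slow for 256³-scale data. A
  vectorized or numba-compiled pass is the natural upgrade path.
- No anisotropic voxel spacing: distances and curvatures are in voxel
  units.
- The renderer is a CPU reference implementation: correct, not fast, and
  its transfer functions are deliberately minimal.
- Graph execution is single-threaded; nodes are pure functions, so a
  parallel scheduler over the topological levels would be straightforward.
- 4D/time-series volumes and out-of-core tiling are out of scope.
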