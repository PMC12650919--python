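# Methods

## Problem and model

The maxillary sinus is an air-filled cavity, radiolucent (dark) on CT,
enclosed by radiopaque (bright) bone. Given a stack of grayscale slices
with intensities in [0, 255], a single seed voxel inside the sinus, and
a global threshold `k`, the pipeline detects the set of voxels belonging
to the cavity and reports its volume as an explicit interval. The method
is fully deterministic: the same inputs always produce the same mask and
numbers.

The central modelling assumption is that segmentation error lives on the
boundary: the thresholded region is correct up to ± one pixel layer per
slice. The lower/upper bound masks encode exactly that assumption, and
the reported `v_mid ± v_err` is the midpoint and half-width of the
resulting volume interval. Nothing in the error model accounts for
gross errors (wrong threshold, leakage through a large ostium), which is
why the seed-on-foreground precondition and the septum-removal step
exist.

## Connectivity conventions

Within a slice, two foreground pixels are contiguous when their L1
distance is 1, so a "surface" is a 4-connected component. Across
adjacent slices, a surface is annexed when one of its pixels is at
in-plane L1 distance ≤ 1 (same (row, col) or a 4-neighbour offset) from
a retained pixel. The fixpoint of the alternating forward/reverse
sweeps therefore equals the 3D connected component of the seed under an
11-neighbour structuring element (in-plane cross, plus same/4-neighbour
offsets across planes); the test suite checks this equivalence against
an independent breadth-first flood fill. Surface labels are numbered by
row-major first appearance so results are reproducible bit for bit.

The sweep scheduler alternates full forward and reverse passes and stops
when a pass adds nothing, with a guard of `2·n_slices` passes (a zigzag
solid can genuinely require about one pass per slice before the final
no-change pass). Exceeding the guard raises rather than silently
truncating.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | global binarization threshold, [0, 255] | none (user) | chosen per scan so the thresholded region matches the cavity |
| `polarity` | which side of `k` is foreground | `foreground_lt` | the sinus is dark; `foreground_geq` provided for completeness |
| `l` | septum-removal layer depth, pixels | 2 | severs channels of width ≤ `l`; 0 disables |
| `window_halfwidth` | in-plane window around reference pixels for contiguity checks | `2l + 1` | bounds where eroded components may be selected |
| `voxel_side L` | cubic voxel edge | from config/DICOM | volumes scale exactly as `L³` |

Volumes default to the cubic-voxel model (`count × L³`, unit label
configurable, default mm³); an anisotropic mode uses `dz·dy·dx` per
voxel from the stack spacing instead. Bound masks are always computed
per slice in 2D — no 3D erosion/dilation — matching the per-matrix
definition of the bounds.

## Septum removal: design choices

* **Erosion** uses the standard plus-shaped structuring element
  including the centre pixel. A formulation conditioning only on the
  four neighbours would let background holes fill during "removal",
  which contradicts the operation's purpose.
* **Reconstruction runs exactly `l` iterations**, not to convergence:
  unbounded geodesic reconstruction would creep back through the severed
  channel and defeat the procedure. Each iteration is a one-step
  dilation constrained to the original mask (growing from boundary
  pixels only is equivalent, since interior pixels have nothing new to
  add).
* **Exactness caveat.** Bounded reconstruction exactly recovers L1
  diamonds of any radius and many digital discs (e.g. diameter 7), but a
  square blob loses its corners (they lie at L1 distance `2l` from the
  eroded core) and digital Euclidean discs at some radii shed isolated
  boundary pixels. In the 3D pipeline this is self-healing: the
  refinement sweeps re-annex such crumbs through inter-slice adjacency,
  and the end-to-end tests confirm exact sphere recovery. The two-blob
  test fixture uses disc-shaped blobs, for which single-slice recovery
  is exact.
* **Degenerate cases.** If erosion empties the mask entirely (`l`
  exceeds the cavity inradius — routine near the top/bottom caps of a
  cavity), the slice is passed through unprocessed with a warning, since
  losing the cavity outright is never intended. If erosion leaves
  material but none of it is contiguous with the references, the
  references connected only through removed layers — i.e. through a
  channel — and the correct result is empty.
* The window restricts **where** contiguity is evaluated; a component
  touched inside a window is kept whole.

## Statistics

Cohen's κ is computed over every voxel of the bounding grid (background
concordance counts), `pe` from both raters' marginal frequencies; κ is
reported as undefined when `pe = 1`. Dice is `2|A∩B|/(|A|+|B|)` over
foreground voxels, undefined when both masks are empty. The consensus
reference is the voxelwise union of the raters. For paired cohorts the
per-sample relative change uses the preoperative volume as denominator;
the summary reports the mean, the sample SD (`n−1`), and a two-sided
Student-t interval at `df = n−1` (for `n = 6`, `t = 2.571`). Percentages
render at one decimal with half-up rounding.

## Phantom generator

Phantoms emulate the geometry and contrast the pipeline faces: dark
ellipsoidal cavities (default intensity 30) in a bright matrix (default
200), optionally joined by axis-aligned rectangular channels of 1–2 px
cross-section emulating the invisible-septum artefact, with optional
additive Gaussian noise (rounded, clamped, seeded). Ellipsoids were
chosen over anatomical meshes because they carry an analytic volume and
an exact lattice count, giving hard oracles. Default study conditions:
a radius-12-voxel spherical cavity in a 40×64×64 stack; pre/post pairs
shrink the primary cavity's semi-axes by factor 0.9 (isotropic true
relative change `1 − f³`); the noise-robustness property uses
`noise_sd = 12` with an intensity gap ≥ 6 SD, mirroring the
well-separated air/bone contrast of CBCT.

What the phantoms do **not** model: anatomical sinus shape, septation
and mucosal thickening, beam hardening, implant metal artefacts, and
partial-volume gradients at the real air–bone interface. Passing tests
therefore demonstrate algorithmic correctness (the implementation
computes what the rules say) and measurement calibration on known
geometry — not clinical accuracy on patient scans, where threshold
choice and manual correction remain the operator's responsibility.

## Problem sizes

The test suite and acceptance script run phantoms between 20³ and
34×48×48 voxels and 1000 random ≤32×32 masks for the brute-force
cross-checks; these sizes give sub-voxel-noise-free oracles while
keeping a full run under a few seconds. Volumes, counts and statistics
are size-exact, not asymptotic, so nothing depends on scaling beyond
these sizes except runtime.

## Known limitations

* A single global threshold `k`; no adaptive or gradient-based
  thresholding, per the method's design.
* Septum removal is strictly per-plane (2D); a channel oriented along
  the slice axis is severed only via the inter-slice adjacency rule.
* The seed-slice septum removal references the seed pixel alone; a seed
  placed within `l` pixels of the cavity boundary falls back to the
  unprocessed seed surface (warned). Choose seeds well inside the
  cavity.
* κ and Dice against expert raters require expert masks; the package
  validates the metrics themselves on constructed cases and phantoms.
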