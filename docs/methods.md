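# Methods

## The forward model

A point γ-source seen through a multi-pinhole collimator casts one inverted
image spot per pinhole onto the detector. Assuming photons travel in straight
lines from the source through each pinhole center, the relation between a
voxelized activity distribution `u ∈ R^M_{≥0}` and the expected detector
image `d_proj ∈ R^N_{≥0}` is linear,

    A u = d_proj,   A ∈ {0,1}^{N×M},

with `A[i, j] = 1` iff a straight line exists from voxel `j` through some
pinhole to pixel `i`. Rays pass through the pinhole *center* (ideal point
aperture), which is what keeps `A` binary; the physical 1 mm aperture
diameter appears only as optional Gaussian blur in the simulator. A ray is
discarded when its angle to the plate normal exceeds the pinhole's half
field of view (45° by default, i.e. a 90° FoV) or when it misses the
detector. A voxel reached through two pinholes landing on the same pixel
keeps a single 1 — `A` stays binary by definition. Septal-wall attenuation,
crystal response and energy thresholding are out of scope.

The column of `A` for a voxel — its **fingerprint** — has at most one entry
per pinhole. `A` is stored as a SciPy CSC matrix, so per-voxel scoring
(`A^T d`, the inner loop of reconstruction) is a single sparse
matrix-vector product and column extraction is a contiguous slice.

### Coordinate conventions

Right-handed frame, origin at the center of the collimator plate, z pointing
into the scene; the detector plane sits at `z = −plane_offset` (default
30 mm — the true plate-to-detector distance of the physical device is not
critical: it only rescales magnification, and every algorithm here is
invariant to it). Detector row 0 / column 0 is top-left; voxel linearization
is x-fastest. The grid is centered on the plate in x/y and its first z-plane
sits one spacing in front of the plate, so the degenerate `z = 0` plane is
never sampled.

### Scale

The full acquisition format is a 1030 × 514 raw frame binned 2×2 (summing
neighborhoods, conserving counts) to 515 × 257 pixels of 0.15 mm pitch
(`N = 132,355`), with a 60 × 100 × 200 voxel grid at 2 mm spacing
(`M = 1,200,000`). Note the literal grid implies a 400 mm z-extent even
though the intended working depth is 200 mm; we keep the literal counts as
the default and expose `n_z`/`spacing` in configuration. Building the
full-scale matrix takes a few seconds; one reconstruction round is ~20 ms —
comfortably inside a ~1.5 s/measurement interactive budget.

Two reduced geometries, sharing the same 38.4 × 76.8 mm physical detector
and collimator, are used for testing and benchmarking (see
`slnf.fixtures`): `tiny` (64 × 128 pixels, 4,800 voxels) is small enough for
pure-Python brute-force oracles; `default` (128 × 256 pixels, 16,875 voxels
at 4 mm spacing) is the benchmark geometry, chosen so the standard
9-position phantom falls exactly on grid points.

### The pinhole pattern

The physical collimator's exact hole arrangement is device-specific and is
treated as a configuration input. The shipped default is a deterministic
jittered 3 × 3 grid of nine 1 mm pinholes spanning the central 60 % of an
80 × 40 mm plate. The span is a deliberate compromise: concentrated enough
that positions in the working volume (y within ±20 mm, z ≈ 120–160 mm) keep
most of their fingerprint spots on the detector, yet wide enough that edge
pinholes drop out of view for off-axis positions — so fingerprint size
(nnz) genuinely varies with position, as it does on real hardware. The
jitter breaks the symmetry that would otherwise give distinct voxels
identical fingerprints.

## Reconstruction (greedy fingerprint search)

Given an observed image `d_obs` and a known number of sources `n`:

1. score every voxel `j` by `C(a_j, d_obs) = Σ_i a_ij · d_obs_i` — for a
   binary fingerprint, the observed counts collected on the footprint;
2. select the argmax voxel (ties broken to the lowest linear index, with the
   tie count reported);
3. set `d_obs` to zero on the winner's footprint, so the next-strongest
   source dominates the next round;
4. repeat `n` times.

Scores are raw counts — no normalization by footprint size; the objective
is a plain inner product. The source count is a required argument; an
optional stopping heuristic (`stop_fraction`: stop when a round's best score
falls below that fraction of the first round's) is provided but off by
default. An all-zero image makes every voxel tie at score 0; the result is
flagged degenerate instead of silently returning voxel 0.

**Identifiability.** On its own noiseless projection a voxel is recovered
exactly iff its fingerprint is not *contained* in another voxel's
fingerprint: any superset column ties under the unnormalized score and the
index tie-break may pick the other voxel. Identical fingerprints are the
special case of mutual containment. `SystemMatrix.duplicate_footprints()`
and `SystemMatrix.ambiguous_footprints()` surface both degeneracies; in the
tiny test geometry ~15 % of visible voxels are ambiguous, essentially all of
them single-pixel fingerprints near the volume edges.

## Assessability (A-optimal design)

For a candidate position with fingerprint `d`, the statistic

    V = trace( d (dᵀd)⁻² dᵀ ) = 1 / (dᵀd) = 1 / nnz(d)   (binary d)

quantifies expected localization difficulty: fewer illuminated pixels mean
less information, so a **higher** score is **harder**. The closed form is
exact (the trace of a rank-1 matrix), so the production path never forms the
N × N matrix; the explicit-trace construction survives only as an
independent oracle in the test suite. Positions with empty fingerprints are
reported as invisible rather than scored. Absolute score values depend
entirely on the collimator pattern; with the default nine-pinhole pattern
they lie in [1/9, 1], not on the 1e−4 scale a many-hole coded aperture
would produce.

## Simulator

The expected image is

    λ = Σ_sources activity · exposure · c · a_col(source)
      + penetration · (source mass, uniformly smeared)
      + hot-background term,

and each repeat is an independent Poisson draw from λ (seeded,
bit-reproducible). Parameters:

- `counts_per_mbq_s` (`c`, default 9.26): calibration constant standing in
  for the physical detection chain (≈10 % quantum efficiency at 140.5 keV);
  chosen so a 15 MBq source at 8 s exposure through nine open rays yields
  ~10⁴ detected counts. Only relative SNR matters to the reconstruction.
- `penetration_fraction` (default 0.075, the midpoint of the 5–10 % wall
  leakage of a thin 3D-printed tungsten collimator): that fraction of the
  total source counts added as a uniform floor over the whole detector.
- `hot_background`: a rectangular volume whose activity (default 120 MBq)
  is split uniformly over the grid voxels it contains and forward-projected
  through `A` — emulating tracer soaked diffusely into the phantom block.
- `aperture_blur_sigma` (binned pixels, default 0): Gaussian blur of λ
  before the draw, modeling the finite aperture diameter.
- an optional saturated-column artifact toggle reproduces a known sensor
  defect, for robustness experiments only (off by default).

Sources snap to the nearest grid voxel; the snap distance is recorded in
the output metadata as the quantization floor. The standard phantom is a
3 × 3 grid in the y–z plane with 20 mm spacing (adjacent pairs 20 mm,
row-end pairs 40 mm, diagonal neighbors 28.28 mm), indexed 1–9, at a
default standoff of 120 mm.

What the simulator does **not** model: scatter and attenuation in tissue,
detector dead time, energy spectra, depth-dependent sensitivity, and the
true (unknown) hole pattern of any particular physical collimator. Passing
tests therefore demonstrate correctness of the algorithms under the stated
forward model, not quantitative agreement with any physical detector's
millimeter error values.

## Evaluation protocol

Each benchmark position is acquired `n_repeats = 10` times (default) at 8 s
exposure; every repeat is reconstructed independently (never an averaged
image) with the true source count; estimates are paired to ground truth by
minimum-total-L2 assignment (Hungarian algorithm — needed because a
two-source reconstruction returns an unordered pair); per-position errors
are summarized by the median and third quartile of the Euclidean distance.
Quartiles use linear interpolation of order statistics at rank
`p·(n−1)+1` (so `[1,2,3,4,5] → median 3, Q3 4`).

### Two-source interference

With ideal point apertures, two grid positions rarely share detector pixels,
so overlapping-fingerprint pairs are constructed from `A` itself
(`interference_pairs`): an anchor voxel, a partner sharing at least one
pixel, and a disjoint partner at the most comparable separation — isolating
fingerprint overlap from source spacing. Masking the first source steals the
shared pixels from the second, which is the mechanism that makes overlapping
pairs harder.

### Noise regimes

At the default calibration (~10⁴ counts/source) localization on the
benchmark geometry is exact at every phantom position — error is limited by
the grid, not by noise. The noise-limited regime begins remarkably low:
recovery stays exact down to ~0.5 expected counts per open ray and degrades
into pure noise by ~0.1. The "low-count" stress condition used for the
assessability–error correlation is therefore fixed at the failure onset,
0.25 expected counts per ray (~2 counts per source), where error first
becomes position-dependent and the information content of the fingerprint
(its nnz) starts to matter.

## Problem sizes used in the shipped benchmarks

Test and acceptance runs use the `tiny` geometry for oracle-exactness
checks (100 random images, every voxel's noiseless recovery) and the
`default` geometry for the phantom benchmarks (9 positions × 20 repeats,
10 interference triples × 10 repeats). The full-scale geometry is exercised
for dimensions and throughput, not for exhaustive scans.

## Known limitations

- The binary ideal-aperture model ignores partial illumination through the
  1 mm holes; a weighted (non-binary) sensitivity matrix is out of scope.
- Greedy extraction with a known source count can hallucinate a second
  source in single-source data (the second score is then small; see the
  stopping heuristic) and inherits the usual greedy failure mode when
  fingerprints overlap heavily.
- No subvoxel refinement: accuracy is floored by the grid spacing.
- Assessability compares positions under one collimator; it is not, by
  itself, a collimator-design optimizer.
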