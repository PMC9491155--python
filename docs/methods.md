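# Methods

This note documents the models, parameters and numerical choices behind
`rhizopore`, and what its synthetic validation does and does not
demonstrate about real scans.

## Imaging model and preprocessing

The unit of analysis is a pair of co-registered 3-D gray volumes of one
soil core at two timepoints, with an isotropic voxel edge length (18 µm in
the motivating scanner configuration; 40 µm in the default synthetic
cores).  Registration is assumed done upstream; a residual rigid error of
about one voxel is tolerated by the dynamics stage.  Preprocessing crops
an interior cuboid (column-wall artifacts), applies a percentile contrast
stretch to 8-bit (default saturation 0.35 % of voxels, split between
tails, following the convention of the common enhance-contrast tool — the
unit of that parameter is genuinely ambiguous, and the choice is recorded
in the provenance log) and denoises.  Denoisers are pluggable: the default
`patch_mean` is the scikit-image non-local means (patch size 3, search
radius 3, h = 6·strength gray levels); `median`, `gaussian` and `box` are
provided.  The pipeline driver defaults to the 3³ median filter, which is
edge-preserving and an order of magnitude faster on full-size volumes
while comfortably halving a noise SD of 8.

## Ensemble pore threshold

Automatic thresholds are unreliable one at a time, so the pore threshold T
is the mean of ten classical histogram methods after removing values more
than one population SD from the raw mean (if all would be removed, all are
kept and a warning raised).  All ten are implemented here on the 256-bin
histogram per their published formulations; where the optimisation
criterion is flat (an empty valley between sharp modes), exact ties
resolve to the middle of the plateau so the threshold lands mid-valley
rather than at the first tied bin.  Five of the methods are cross-checked
against scikit-image in the test suite on histograms with populated
valleys, where the optimum is unique.

Binaries derived from T use the inclusive tie rule `pore: g ≤ T`.  The
organic band `T/2.4 < g ≤ T` holds roots, water and particulate organics;
the divisor 2.4 is exposed as a parameter since it depends on scan
contrast.

## Tubular segmentation

Roots are segmented from the organic binary and biopores from the pore
binary with an identical multiscale chain, so both classes are treated
consistently across their size range:

1. **Speckle opening (roots only).**  Granular fauna-cast infills scatter
   organic-gray grains through the organic band; a one-voxel binary
   opening removes this voxel-scale speckle while compact root tubes
   survive.
2. **Downscale** by mean pooling to 50 % and 20 % of resolution
   (fractional occupancy preserves thin structures better than
   nearest-neighbour decimation).
3. **Tubeness** at σ = 1–4 (50 % band) and σ = 2–30 (20 % band), step 1:
   the bright-tube Hessian measure σ²·√(λ₂λ₃) where both eigenvalues are
   negative, multiplied by a cylindricity gate `1 − |λ₁|/√(λ₂λ₃)` that
   suppresses compact blob bodies (three comparable negative eigenvalues)
   without touching ideal tubes (axial eigenvalue ≈ 0).
4. **Scale-fair binarisation.**  The response is normalised per σ by the
   centerline response of an ideal solid cylinder of diameter 2σ
   (precomputed on a 2-D cross-section, since an infinite cylinder's
   in-plane Hessian equals the smoothed disk's) and thresholded at 0.5.
   Because that cutoff only captures the core of a tube, each seed is
   grown by a ball of its own best scale before intersecting the input
   binary, recovering the full cross-section.
5. **Watershed splitting.**  Distance-transform watershed with
   scale-adaptive ridge markers: the EDT is lightly smoothed (σ = 1.5, to
   kill voxelisation ripple) and a voxel seeds a ridge when nothing within
   about twice its inscribed radius is more than one voxel higher.  A
   uniform tube then carries one connected marker while a thin lateral
   joining a thick trunk separates near the junction.
6. **Blob filtering.**  Per segment, elongation = geodesic skeleton length
   / mean skeleton calibre; segments below 2 are removed.  The geodesic
   (longest-path) length is used because the thinning skeleton of a
   compact body is a medial shell whose total edge length is meaningless.
7. **Tube refit (biopores).**  The paper-gap here is that biopores must be
   separated from elongated strands of the irregular pore network, which
   are locally just as tubular.  For each kept segment the skeleton is
   pruned to its thick core (calibre ≥ half the subset's 90th percentile,
   re-evaluated recursively so a thin tube merged with a thick one keeps
   its own backbone), backbones are extracted by iterative longest-path
   peeling, extended past the thinning end-erosion, and a smooth calibre
   profile (running max + median over 7 nodes) defines the refit tube.
   Backbones whose median calibre falls below the biopore calibre floor —
   max(0.5 mm, two coarse-band voxels) — or whose length is under two
   diameters are discarded; the floor encodes that biopores at the
   earthworm/taproot scale cannot be reliably told apart from pore-network
   strands below the scale at which the coarse band resolves them.
   Remaining attached wall junk falls outside the refit surface and is
   dropped.  Roots skip the refit and calibre floor: the organic binary
   contains no irregular pore network.

On the default synthetic study core this chain reaches voxel precision and
recall of ~0.93–0.96 for biopores and roots against the planted truth.

## Local thickness and size distributions

Local thickness is the diameter of the largest sphere inscribed in the
mask containing the voxel.  The implementation iterates candidate radii
(descending): centres are `EDT ≥ r`, coverage is `distance-to-centres ≤ r`,
and a voxel takes twice the largest covering radius.  Squared EDT values
are integers, so all comparisons are integer-exact and the result equals
the exhaustive inscribed-sphere search including boundary ties (verified
per run against a brute-force oracle on random masks).  Masks with more
than 512 distinct radii switch to 0.5-voxel radius quantisation; each
centre still covers with its own (quantised) radius, so radii are biased
down by at most half a voxel, though a thin shell at each sphere boundary
may fall to the next covering sphere (mean error below one voxel of
diameter on test masks).

Size distributions are volume-weighted thickness histograms on the
left-open, right-closed classes 0.036 / 0.2 / 0.5 / 1 / 2 mm / ∞ (roots:
0.036 / 0.2 / 0.5 / 1 / ∞), with sub-resolution voxels reported
separately; class volumes sum to the mask volume exactly.  Mean diameters
are volume-weighted means of the thickness map.

Root length uses the 3-D skeleton traced into branch paths: coordinates
are smoothed (window 5) to remove the digital zigzag bias that inflates
oblique lines, spur branches hanging off junctions are pruned when shorter
than ~1.3 local radii *and* surface-hugging at the tip (a genuine tube end
carries a full end-cap radius), and free ends are credited the thinning
end-cap erosion (EDT − 1).  Straight test cylinders measure within ±1 %,
tortuous tubes within about ±7 %.

## Temporal dynamics

Turnover masks come from differences of segmented masks with the
subtracted mask dilated by a Euclidean ball (default radius 1 voxel, the
stated tolerance for registration jitter and small thickness changes),
followed by removal of 26-connected components below 0.3 mm³ (components
at or above the cutoff are kept; at 18 µm voxels the cutoff is 51,440
voxels).  Two consistency rules sharpen the raw subtraction:

* biopore turnover is a material change, so a candidate destroyed/created
  component still lying mostly (> 50 %) in the other timepoint's *stable*
  pore space — the pore binary after a one-voxel opening, which erases the
  speckle porosity of granular casts but keeps open channels — is
  segmentation flicker, not turnover, and is dropped;
* newly grown root tubes are excluded from the created-biopore source, and
  the destroyed mask is excluded from the new-root difference (granular
  cast partially leaks into the organic band; a cast infill is not a
  root).  The new-root difference itself is taken against t1 *roots*, so a
  root threading an old air-filled biopore is still detected.

## Structure labels, trajectories, cast agents

Per-voxel structural labels combine the masks with precedence old root >
biopore > macropore (pore minus biopore minus root) > matrix.  New-root
trajectory fractions are voxel lookups of the t1 label under the new-root
mask, reported both in four classes and with old-root voxels folded into
matrix (old roots are a class the three-component view leaves
unaddressed); fractions are volume-based.

Destroyed-biopore infills are attributed to earthworm cast (large,
smooth, bright), mesofauna cast (granular speckle) or unidentified
(compaction/erosion) agents.  Features per voxel and scale (σ = 1, 2, 4):
Gaussian intensity, gradient magnitude, Laplacian, largest
structure-tensor eigenvalue, local variance.  A 100-tree random forest is
trained on sparse stratified annotations (in synthetic studies, 0.1 % of
destroyed voxels per class drawn from the ground truth, emulating manual
scribbles) and reports its out-of-bag error; "unidentified" is a trained
class, not a rejection threshold, and the per-segment vote fraction is
exported so users can impose one.  Segments from the distance-transform
watershed take their majority class; ties break deterministically to the
lowest class code and are flagged.

## The synthetic core generator

The generator is first-class, tested code.  It emulates what the pipeline
assumes about real scans: a bright mineral matrix (gray 180), dark
air-filled pores (20), intermediate organics (90), a smooth bright
earthworm-cast texture (200), a mesofauna cast rendered as a 50/50 speckle
of 90/180 at two-voxel granularity, and additive Gaussian noise (default
SD 8 on 0–255).  Irregular pores are a thresholded Gaussian random field
(smoothing 3 voxels) hitting a target volume fraction exactly; roots and
biopores are swept spheres along smoothed random walks (downward drift,
lateral reflection); roots avoid fusing with each other since real roots
cross but do not merge.  The default configuration is the full study core:
200³ voxels at 0.04 mm, 15 % blob porosity, ten biopores of 0.8–2 mm,
twenty roots of 0.2–0.5 mm — note this implies a bioporosity (~9 %) far
above typical field topsoil (~2 %), a deliberately structure-rich regime
that exercises every pipeline stage in one core.

Second-timepoint dynamics are planted by construction: agents consume
successive arc intervals of shuffled biopores until per-agent volume
budgets (default: 30 % of biopore volume destroyed, split 0.4 / 0.4 / 0.2
earthworm / mesofauna / unidentified) are met to within a few voxels;
created biopores burrow through matrix and blob pores but not existing
tubes; new roots realise planned trajectory fractions (default 15 % into
biopores / 40 % into macropores / 45 % into matrix, the magnitudes
reported for second-season growth in the motivating field system) via
three mechanisms — roots threading existing biopores (volume trimmed to
the target exactly), matrix walks whose incidental blob crossings are
accounted, and compact "macropore chambers" carved on the matrix paths,
widely spaced so a chamber chain never reads as one cylindrical cavity.
An optional whole-voxel rigid shift with fresh noise realises registration
jitter.  All randomness derives from one seed; identical specs give
bit-identical volumes, and every planted summary is recomputable from the
label grids by voxel counting.

What passing tests on these phantoms does *not* show: robustness to beam
hardening, ring artifacts, partial-volume blur (grays are flat per
material, so histograms are cleanly multimodal), non-rigid registration
error, or realistic aggregate morphology.  The acceptance quantities are
properties of this synthetic regime, not reproductions of any field
measurement.

## Validation statistics

The CT-vs-reference root length comparison uses a no-intercept least
squares fit (slope = Σxy/Σx²); the reported R² is about the mean of y —
no-intercept R² is convention-dependent, and the convention is named in
the output header.  Correlation screening computes all pairwise Pearson
coefficients with two-sided p-values and flags p < 0.01.  Mixed-model
group comparisons are deliberately out of scope; the per-core summary
CSVs are export-ready for any statistics environment.

## Problem sizes and runtime choices

The package targets single-CPU analysis.  Default validation sizes: the
200³ study core for segmentation/dynamics/trajectory/agent checks, ten 96³
cores for the root-length regression, 96³ cores for jitter and
reproducibility checks, and ≤ 40³ masks for the thickness oracle (the
exhaustive oracle is quadratic and exists to be slow).  The dual-band
tubeness, one full-grid EDT per refit, and per-radius thickness iterations
dominate runtime; a 200³ core segments in under a minute per timepoint.
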