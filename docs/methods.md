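# Methods

## Data model

An **event list** is the raw SMLM product: per localization a camera
frame index, a 3D position in nm and optionally a photon count. Vendor
exports differ only in column names and units, so reading goes through a
dialect mapping (default headers `frame`, `x[nm]`, `y[nm]`, `z[nm]`,
`intensity`; a `scale` entry converts file units to nm). All internal
coordinates are nm. Condition and cell membership are declared in a
manifest file (`condition`, `cell_id`, `path`, optional
`fiducial_path`) rather than parsed from filenames.

## Drift correction

Stage drift is estimated from fiducial beads that emit every frame. The
pooled fiducial events are split into per-bead tracks by single linkage
at 500 nm; the displacement at frame *f* is the mean over tracks of
(position at *f* − position at the track's first frame), interpolated
over unobserved frames and smoothed with a 50-frame moving average, then
subtracted from every event. If two bead tracks overlap spatially they
merge into one; because all beads share the same drift this only adds a
constant offset to the estimate, i.e. a global translation of the
dataset, which is immaterial to every downstream statistic. The residual
RMS of the corrected fiducials is reported.

## Blink merging

One fluorophore blinks several times, so raw events overcount
molecules. Merging iterates to a fixpoint: build the proximity graph
with edges between events at distance ≤ *t* (the merge threshold,
default 20 nm; ties count as edges), replace every connected component
by its event-count-weighted centroid, repeat. The contraction rule is
order-independent and deterministic, conserves mass (node weights sum to
the event count), terminates (the component count strictly decreases or
the loop stops), and guarantees all pairwise node distances > *t*.
Event-to-node provenance is kept so simulations can score nodes against
ground truth.

### Resolvability

Merging can only recover the true molecule count when neighbouring
blink clouds do not bridge. For two molecules at distance *d* with
per-axis localization error σ, a given blink pair falls within the
threshold *t* with probability P(χ'²₃(d²/2σ²) ≤ t²/2σ²) (noncentral
chi-square); with ~5 blinks per molecule there are ~25 such pairs. At
σ = 5 nm and t = 20 nm this bridging probability is ≈ 0.98 at
d = 25 nm, 0.19 at 35 nm and < 10⁻⁴ at d ≥ 50 nm. The package's
molecule-count-recovery condition (`smlmnet.simulate.recovery_spec`)
therefore places its 144 molecules with a 50 nm separation floor
(threshold + ~6× the blink-pair spread σ√2) on a shell large enough for
that floor to be feasible (radius 250 nm). Under these conditions the
mean recovered count is ≈ 145: bridging is negligible and the small
excess over 144 comes from molecules with exactly two blinks drawn
> t apart, which split irrecoverably (expected ≈ 1.4 per blob at
σ = 5 nm). Exact per-seed recovery requires σ ≲ 3 nm.

## Denoising

Each node's degree in the proximity graph at radius *r* (default 50 nm)
is compared with the pooled degree distribution of `null_reps` (default
10) uniform point sets of matched count in the event-list ROI box — a
matched-intensity spatial Poisson null. The threshold d* is the
`retain_quantile` (default 0.95) quantile of the null degrees; nodes
with degree > d* are retained. In sparse scenes d* is typically 0, so
the filter removes exactly the isolated background nodes; in dense
scenes the retained fraction of a uniform cloud approaches
1 − `retain_quantile` up to the discreteness of integer degrees. Nodes
are never invented, only removed; the kept-index map is reported.

## Segmentation

Flat-kernel mean shift at bandwidth *h* (default 180 nm), seeded at the
centres of occupied 40 nm grid bins anchored at the cloud's minimum
corner — which makes the result deterministic, node-order independent
and translation invariant. Nodes beyond the reach of any mode and
basins smaller than `min_blob_size` (default 5 nodes) are marked
unassigned and excluded downstream. Blobs are indexed in decreasing
size. The bandwidth default tracks the generator's blob scale: a flat
kernel needs *h* at least the blob radius to find one mode per blob
(caveola-like blobs here are ~250 nm across; at 120 nm bandwidth the
shells fragment, at 180 nm segmentation reproduces ground truth with
ARI 1.0), and *h* must stay below the inter-blob clearance.

## The 28 blob descriptors

The registry (`smlmnet.features.FEATURE_NAMES`) fixes 28 named, ordered
descriptors: node count; per-axis extents; covariance eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ (floored at 10⁻⁶ nm² for degenerate blobs, with a flag);
enclosing-ellipsoid volume with semi-axes 2√λᵢ (≈ 95 % of a Gaussian's
mass — a convention, fixed here); point density; Westin anisotropy
measures — linear (λ₁−λ₂)/Σλ, planar 2(λ₂−λ₃)/Σλ, spherical 3λ₃/Σλ
(summing to 1) and fractional anisotropy √(3/2)·‖λ−λ̄‖/‖λ‖; four
distance-to-centroid statistics; and network features of the blob's
proximity graph at the denoising radius — edge count, four degree
statistics, density, greedy-modularity modularity and module count,
mean clustering coefficient, characteristic path length on the largest
component — plus the shrink-0 (convex-hull) volume. All descriptors
except the three axis-aligned extents are invariant under rigid
rotation; all are translation invariant. The registry is data-driven so
an alternative published feature set can be swapped in without touching
the extraction code.

## Group discovery and class matching

Features are z-scored per condition (σ floored at 10⁻¹² for constant
columns) — required for scale-free Euclidean geometry across units (nm,
nm³, counts). X-means starts at `kmin` k-means centroids and repeatedly
attempts a 2-split of each cluster, accepting a split iff the local BIC
of the two-child model exceeds the parent's, with a full k-means
refinement pass after each accepted round, stopping at `kmax`. The BIC
is the spherical-Gaussian identical-variance form
(ℓ̂ − ½·p·log n with p = (K−1) + K·d + 1 and an unbiased pooled
per-dimension variance). Inner k-means runs use k-means++ with 10
restarts and seeds derived deterministically from the configured seed.
On clean Gaussian structure X-means recovers the generative K; on real
feature matrices the local criterion tends to over-split, which is
harmless here because groups are matched many-to-one onto reference
classes.

Matching assigns each group centroid the reference class at smallest
Euclidean distance, with ties resolved to the lowest-index class (and
logged) and many-to-one mappings flagged. Reference centroids are an
input table in raw feature space, projected with the condition's
z-scoring parameters; for self-contained runs
`reference_from_simulation` computes them from a labelled synthetic
calibration scene. Clustering is per condition by default
(configurable), mirroring separate group tables per condition with a
common reference.

Silhouette means per group diagnose the clustering; they are undefined
(None) at K = 1.

## Boundaries and shrink factor

A blob boundary is a watertight surface through a subset of the blob's
nodes enveloping all of them, parameterized by a shrink factor
s ∈ [0, 1]: s = 0 is the convex hull (most convex), s = 1 the tightest
single-region boundary (most indented). From the Delaunay
triangulation, simplices removable without breaking single-region
envelopment are those whose circumradius exceeds the critical alpha —
the smallest circumradius threshold at which the kept complex is
face-connected and covers every input point. The removable simplices,
ordered by descending circumradius, form the candidate set; shrink s
removes the leading fraction s (rounded). Volume is the sum of kept
simplex volumes, equal to the signed-tetrahedron sum over the surface.
Consequences, all asserted in tests: volume is non-increasing in s;
every input point stays on or inside the boundary at every s; s = 0
matches an independent convex-hull computation to 10⁻⁶ relative.

Numerical choices: circumradii of near-degenerate (sliver) simplices
use a least-squares circumcentre, which reduces to the in-plane
circumcircle in the coplanar-cocircular limit; radii equal to within
10⁻⁹ relative share a removal level, so symmetric configurations (e.g.
a cube's six tetrahedra on one circumsphere) are never partially
carved; at intermediate s a kept simplex above the critical alpha can
be face-isolated, in which case the single-region flag is reported
False. Collinear/coplanar inputs raise an error naming the degeneracy.
The 2D variant applies the same semantics to triangles of the XY
projection and returns the outer boundary loop counter-clockwise.

PCA projection for blob display centres the nodes and rotates onto
covariance eigenvectors ordered by descending variance; each axis is
oriented so the skewness of the projected coordinates is ≥ 0 (at zero
skew, so the axis's first nonzero component is positive), making
projections reproducible across rigidly rotated copies.

Representative blobs are, per cell, the N (default 10) blobs whose
z-scored feature vectors (condition-wide scaling, all 28 features) lie
closest to the condition mean, ties broken by blob id. Volume
statistics use the unbiased (n−1) sample variance; groups with fewer
than two blobs are flagged.

## Condition statistics

Blob features are averaged per cell (and per cell × class), and
conditions are compared feature-wise with Welch's two-tailed unpaired
t-test — the unequal-variance form is the safer default when only "an
unpaired two-tailed test" is specified. Percent change is
100·(mean_B − mean_A)/mean_A. No multiple-testing correction is applied
by default; Benjamini–Hochberg is available as a flag. Conditions with
fewer than two cells are rejected.

## The synthetic generator

`SimulationSpec` describes one cell: per-class blob geometry and counts,
a minimum molecular separation floor (dart throwing with a retry cap),
blink multiplicity 1 + Poisson(μ_b − 1) (default μ_b = 5, keeping every
detected molecule's blink count ≥ 1 with one parameter), anisotropic
Gaussian localization error, uniform background monomers, detection
efficiency, linear or random-walk drift observed through fiducials, and
condition modifiers (global scale, elongation along a random axis,
outward protrusion of a molecule fraction — emulating labels extending
away from the domain surface).

Class defaults place molecules at the scale the imaging system
resolves, which is also the regime real merged point clouds occupy
(their nodes are pairwise > 20 nm apart by construction): caveola,
spherical shell r = 120 nm with 144 molecules (the canonical caveolar
copy number); S2, hemispherical shell r = 120 nm, 60 molecules; S1B,
two-lobed cluster of 55 nm balls, 35 molecules; S1A, 50 nm ball, 15
molecules; 25 nm separation floor; σ_lateral = 7.5 nm and
σ_axial = 16 nm (lateral/axial resolution ranges of 15–20 and
25–50 nm FWHM, midpoints ÷ 2.35); background 2 monomers/µm³. Post-merge
node counts are ≈ 95/60/25/12 per class, well ordered for class
discovery, and the smallest class stays above the 5-node minimum blob
size. Scaffold molecule counts are placeholders ordered by class size;
they are configurable where a calibrated value exists.

What the generator does *not* emulate: on/off blink kinetics and frame
correlation, PSF shape and camera noise, antibody linkage geometry,
molecule-density gradients, or spatially varying background. Passing
tests therefore demonstrate correctness of the analysis under the
stated statistical model, not performance on any particular microscope's
data.

## Problem sizes

Default test scenes use 2 blobs per class per cell (≈ 3 000 events per
cell) and 2–4 cells per condition; the molecule-count-recovery study
uses 50 replicate blobs; the four-group discovery study uses 100 seeds
of 4 × 50 points in 28 dimensions. These sizes make the full suite and
the acceptance script run in minutes on one CPU while keeping every
statistical check well-powered.

## Known limitations

- The denoise null is a homogeneous Poisson box; structured background
  (e.g. membrane-correlated monomers) would need an inhomogeneous null.
- Paired two-node artifacts from split blink clouds can pass the degree
  filter in sparse scenes; they are removed later by the minimum blob
  size.
- X-means with the local BIC criterion over-splits non-Gaussian
  feature clouds (absorbed by many-to-one class matching).
- Blink merging is frame-agnostic; no frame-gap-aware linking.
- The boundary at intermediate shrink factors interpolates by removal
  count, not by a geometric quantity; only s = 0, 1 have
  parameter-free meaning.
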