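# Methods

## What the package models

`interdigitate` implements, end to end, a within-individual
functional-connectivity analysis for surface fMRI: deeply sampled single
subjects (many sessions each, split into discovery and replication
halves) are used to show that a canonical distributed brain network in
fact fractionates into two parallel networks whose regions lie side by
side — interdigitated — within many cortical zones. Because the real
multi-session human data behind this design are not publicly deposited,
the package pairs the analysis chain with a synthetic-data generator
that plants that exact spatial structure with known ground truth, so
every stage can be validated quantitatively.

## Surface model

Each hemisphere is an icosphere: a recursively subdivided icosahedron
projected to the unit sphere, with `10 * 4^L + 2` vertices at
subdivision level `L`. Level 6 reproduces the 40,962 vertices per
hemisphere of the standard high-resolution template (81,924 vertices
over both hemispheres, the dimension of the full vertex-wise
connectivity matrix). The two hemispheres are identical registered
spheres with disjoint vertex blocks and no connecting edges; all
analyses treat them as one vertex set, left hemisphere first. Desk-scale
analyses default to levels 2–4 (162–2,562 vertices per hemisphere); a
guard refuses dense vertex-by-vertex matrices above 20,000 vertices, and
a row-streaming path (`mean_z_rows` / `mean_z_row_view`) computes only
the seed rows needed by the seed search at higher resolutions.

## Synthetic-data generator

Signal model per vertex `v`, frame `t`:

    x_v(t) = baseline + sum_k w_vk * s_k(t) + g(t) + eps_v(t)

* `s_k`: independent unit-variance latent network time courses. White
  noise is brick-wall filtered in the frequency domain below
  `latent_lowpass_cutoff` (default 0.08 Hz) and re-standardized, so the
  "all power is low frequency" property holds exactly and the planted
  signal survives the preprocessing filter by construction.
* `w_vk = network_loading` on the support of network `k`, else 0;
  optionally multiplied by `dropout_attenuation` inside a designated
  dropout zone (signal only — noise is unaffected), emulating
  susceptibility loss.
* `g`: a global white-noise signal shared by all vertices (recorded in
  the nuisance table, alongside six smooth synthetic "motion"
  regressors that do not enter the data).
* `eps_v`: white vertex noise, sd `vertex_noise_sd`.
* `baseline` (default 200) sets the mean signal level and hence the
  tSNR scale; it is removed by the regression intercept downstream.

Templates plant `n_networks` (default 2) networks across `n_zones`
(default 6) geodesic-disc zones placed by farthest-point sampling.
Inside each zone the networks' parcel anchors are mutually adjacent
vertices, and zone vertices join the nearest anchor's parcel within
`parcel_radius` hops — a Voronoi-style partition that makes parcels
disjoint with shared borders (the interdigitated arrangement). Zone 0
plays the role of the lateral-prefrontal search zone; the remaining
zones are the distributed test zones. Per-subject jitter moves each
anchor by a random walk of `jitter_steps` hops inside its zone
(collisions rejected), emulating idiosyncratic region positions across
individuals; `jitter_steps = 0` consumes no randomness, so all subjects
share one template. The study layout is 4 subjects x 24 sessions at
TR = 1 s with 422-frame runs by default; odd-numbered sessions form the
discovery half, even-numbered the replication half. All randomness
derives from `master_seed` via seed sequences, making the generator a
pure function of its parameters.

What the generator does **not** emulate: hemodynamic convolution,
head motion and motion correction, spatially structured (1/f or
distance-dependent) noise, cortical folding geometry, non-stationary
network dynamics, and graded network membership (loadings are binary on
parcel supports). Passing tests therefore demonstrate that the analysis
chain recovers planted structure of this idealized kind at realistic
SNR; they do not certify performance against physiological artifacts.

## Preprocessing

Stage order (a config switch exists, the default follows the published
step order): discard the first 12 frames (T1 equilibration), temporal
low-pass at 0.08 Hz, nuisance regression, surface smoothing at 2 mm
FWHM.

* **Filter**: zero-phase Butterworth of order 5 applied
  forward–backward (`sosfiltfilt`) on demeaned series, mean restored
  exactly afterwards. Order 5 was chosen so the double pass keeps a
  0.05 Hz component within 1% amplitude while attenuating 0.20 Hz by
  ~5 x 10^-4; a 4th-order double pass would already lose 2.3% in the
  pass band. Nuisance regressors are filtered identically — regressing
  unfiltered regressors against filtered data leaves a large shared
  residual and spuriously inflates between-network correlations.
* **Nuisance regression**: intercept + regressors (+ backward-difference
  temporal derivatives with a leading zero, doubling the count —
  e.g. the canonical 9-regressor fMRI set becomes 18 + intercept).
  Exact least-squares projection; a pivoted-QR rank check rejects
  collinear designs and names the offending columns.
* **Smoothing**: iterated graph diffusion `x <- x - tau * L x` with the
  combinatorial Laplacian `L = D - A`, which preserves the per-frame
  vertex sum exactly and cannot mix hemispheres. The schedule solves
  `n * 2 * tau = sigma_hops^2` with `tau <= 1/12` (stability), so
  sub-edge kernels get one proportionally small step rather than a
  full-edge one. The FWHM-to-hops conversion uses a nominal edge length
  of `1.4 mm * 2^(6 - level)` — anchored to the ~1.4 mm spacing of the
  40,962-vertex template — so "2 mm FWHM" means the same physical
  smoothing at any desk-scale resolution. An explicit `mesh_edge_mm`
  overrides this.

QC maps are computed on raw (unfiltered) data: tSNR = mean/sd over time
(sd with denominator T-1; zero-variance vertices flagged undefined, not
infinite) and fALFF = spectral amplitude in 0.01–0.08 Hz over the total
DC-excluded amplitude. "Power" is operationalized as amplitude (square
root of the periodogram) summed over one-sided periodogram bins, per
the originating method; a raw-power option exists. For white noise at
TR = 1 s this gives fALFF near (0.08 - 0.01)/0.5 = 0.14.

## Connectivity

Per-run Pearson correlation over all vertex pairs, Fisher r-to-z, then
elementwise averaging over runs (summed in canonical run order, so the
result is bit-identical under input permutations). Self-correlations are
stored as the sentinel `atanh(1 - 1e-7) ~= 8.41` and excluded from all
statistics; zero-variance vertices are masked. Seed maps are rows of the
mean z matrix, annotated with the display range [0.2, 0.6] used in the
original interactive exploration. The discovery/replication split-half
consistency is the Pearson correlation of the two mean matrices' upper
triangles.

Reliability-based disattenuation (for dropout-affected cortex): the
across-run reliability of a seed's FC map is operationalized per vertex
as ICC(1,1) with runs as raters and the vertex plus its 1-hop neighbors
as items, clipped to [0, 1] and requiring >= 3 runs. This construction
is a declared stand-in — the analysis it emulates cites a reliability
method without printing a formula — chosen because it measures
across-run agreement with local spatial support and is naturally
bounded. The corrected map is `z / sqrt(max(reliability, floor))`
(classical correction for attenuation with one unreliable side), floor
0.04 so empty reliability never multiplies by more than 5.

## Seed search

The interactive procedure is made criterion-driven and exhaustive. A
candidate seed's map is summarized by its peak z per zone (the seed
vertex itself excluded); the verdict is **robust** when at least
`min_zones` (default 4, the four-lobe motif of the canonical network)
zones peak at or above `z_robust = 0.6`, otherwise **diffuse** when the
global peak reaches `z_diffuse = 0.4` (signal mixing), else **dropout**.
The first seed is the robust candidate with the most robust zones, ties
broken by stronger mean zone peak and then lowest vertex index (the
map-strength judgment of the interactive procedure made explicit; a
pure index tie-break is arbitrary once the zone count saturates). The
second seed must lie in the search zone, within `vicinity_hops` of the
first (unset = anywhere in the zone; no distance is published), show
z < `z_separation = 0.3` with the first seed, and itself be robust.
Failures raise errors that name the criterion that eliminated the last
candidates. Whether the published ~0.6 / ~0.4 values were hard
thresholds is unknowable; they are implemented as configurable hard
thresholds with those defaults.

## Dissociation battery

A priori regions are single vertices fixed on discovery data only: per
test zone, the network-A target maximizes `z(seed_A) - z(seed_B)` and
vice versa. A provenance firewall enforces the split: region sets carry
a "discovery" label and the extraction step rejects any session from
the discovery half. Each replication session contributes one Fisher-z
per (seed, target) cell; with 12 replication sessions the 2x2 design is
balanced with n = 12 per cell. The two-way fixed-effects ANOVA is the
classical balanced sums-of-squares decomposition (authored in-package;
an independent OLS-based fit serves as the test oracle), F tested on
(1, 4(n-1)) degrees of freedom against the exact F distribution.
Crossover classification: **crossover** iff mean(A->A) > mean(A->B) and
mean(B->B) > mean(B->A); **ordinal** iff the interaction contrast
AA - AB - BA + BB is positive but one inequality fails; **none**
otherwise (ties included). No multiple-testing correction is applied
across the 20 tests — the design argues by convergence of repeated
significant results — but every report carries the family-wise null
expectation (alpha x tests) for transparency. A lone single-network
region (the parahippocampal case) is expressed by pairing it with the
opposite network's region from a partner zone, which reduces it to an
ordinary 2x2 entry.

## Parcellation

Vertex time series from the discovery half are concatenated in time,
z-scored per vertex (zero-variance vertices left at zero), and
clustered with k-means (k-means++ initialization, best of `n_restarts`
(default 10) by inertia, fixed seed; Euclidean distance on z-scored
rows, which is correlation distance up to scale — the original MATLAB
settings are unpublished, so these defaults are declared, not
inferred). The pipeline default is k = 12, the low-dimensional
fractionation used for confirmation; recovery scoring uses k matched to
the planted structure plus background. Scoring: the one-to-one
cluster-network assignment maximizing total overlap is solved exactly
(Hungarian algorithm) over {background, networks}; adjusted Rand index
is computed over all vertices and Dice per matched network.

## Misalignment

Each subject's 10 regions (2 networks x 5 zones: the seed pair plus
four test-zone pairs) define a 10x10 matrix of session-averaged
region-pair z on replication data. Cross-subject transfer applies
subject i's region vertices to subject j's data directly — meshes are
registered by construction, mirroring surface-registration-based
transfer. Breakdown is quantified by (a) the block contrast, mean
within-network off-diagonal z minus mean between-network z, and (b) the
accuracy of a two-cluster spectral sign split of the matrix against the
network labels. With jitter at parcel-radius scale, own-subject
contrasts exceed cross-subject contrasts essentially always; with zero
jitter the two are indistinguishable, confirming the degradation is
caused by spatial variability alone.

## Problem sizes and numerical choices

Desk-scale runs used throughout the tests and the reproduction script
(chosen once as realistic for a single CPU, and stated here as the
package's own configuration):

* powered dissociation battery: level 3 (642 vertices/hemisphere),
  4 subjects x (12+12) sessions x 300 frames, loading 1.0, noise sd 1.0;
* battery structure check: level 4 (2,562 vertices/hemisphere), same
  design, streamed one subject at a time via seed-row connectivity;
* type-I calibration: 500 null studies (loading 0) at level 2 with
  12 replication sessions x 128 frames and well-separated arbitrary
  regions — 10,000 interaction p-values;
* misalignment: 100 replicate 4-subject studies at level 3 with
  (6+6) sessions x 200 frames, jitter = parcel radius = 2;
* parcellation recovery: level 3, 12 discovery sessions x 300 frames,
  k = 3 (two networks + background).

Numerical details: Fisher z clips |r| at 1 - 1e-7; correlations are
clipped to [-1, 1] before the transform; run averaging uses a fixed
summation order; k-means and the jitter walk take explicit seeds;
degenerate inputs (zero-variance vertices, rank-deficient designs,
empty zones, short runs) raise typed errors rather than propagating
NaNs. Null-study regions are placed by farthest-point sampling because
the F test's independence assumptions require region pairs that do not
share smoothed neighborhoods; adjacent regions (as real paired regions
are) induce within-session covariance between cells, which the balanced
ANOVA does not model.

## Known limitations

* The generator's idealizations listed above; in particular real
  signal dropout, motion and physiological noise are absent.
* At desk scale parcels are only a few hops wide, so smoothing-induced
  boundary mixing is proportionally larger than on the full-resolution
  template; the level-derived edge length keeps the 2 mm kernel small
  for exactly this reason.
* Matrix-wide split-half consistency on synthetic studies runs slightly
  below the values reported for real cortex (~0.8 vs 0.87–0.95) because
  planted structure covers ~10% of vertices and the remaining matrix is
  pure sampling noise.
* The ICC-based reliability map is a stand-in for an uncited formula;
  disattenuated values should be read as a sensitivity analysis, not a
  calibrated correction.
* The seed-search thresholds encode printed values from an interactive
  protocol; on data with different z scales (e.g. different run
  lengths) they may need re-tuning via `SeedCriteria`.
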