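# Methods

This note records the statistical models behind `miisr`, the conventions
and defaults chosen where several were defensible, what the synthetic
generators do and do not emulate, and known limitations.

## Data model

A `LocalizationTable` holds one colour channel: x/y (optionally z)
coordinates in nanometres, photon counts and per-molecule localization
precision where the instrument exports them. Row order is meaningless and
every operation is permutation-invariant. Vendor exports are converted by
linear pixel→nm and intensity→photon scaling applied identically to all
records, followed by quality filters (`min_photons`, `max_precision`).
Records without precision values are kept but cannot contribute to
precision-derived statistics. The vendor column layouts ship as editable
presets because instrument software versions drift; `generic_tabular`
with an explicit column map is the fallback.

## Colocalization distance criterion

CDC = m·σ_RMS + I_reg with σ_RMS = √(Σσ_cᵢ²) over the 2–3 channels,
m ∈ {1.65, 2}. The root-mean-squared form is used because only it
reproduces the expected 23–28 nm two-colour CDC from ~10 nm per-channel
precisions; a `literal_sum` compatibility flag computes √(Σσ_cᵢ) for
comparison against legacy software that printed the non-squared form.
σ_cᵢ defaults to the mean of the channel's per-molecule precision column
and can be overridden when that column is absent.

## SAA

Nearest-neighbour distances are exact (k-d tree). The SRP control
randomizes only the target channel of each direction, uniformly over the
analysis region — by default the joint bounding rectangle, optionally
the convex hull of the molecules ("minimum bounding polygon"), which
prevents over-estimation of association when a loose ROI includes
unoccupied area. SRP fractions are averaged over `n_randomizations`
(default 20; the appropriate count is not canonical, and 20 keeps the
Monte-Carlo error on the SRP fraction well below biological effect
sizes). The histogram mode uses 2 nm bins over [0, 200] nm, the mode
being the centre of the highest bin with ties broken toward smaller r:
2 nm resolves the oligo-duplex separations (≥ 2.6 nm apart) without
chasing jitter noise.

Homotypic (same-channel) SAA is possible but warns: repeat detections of
one fluorophore are indistinguishable from genuinely adjacent
fluorophores. Three-colour SAA classifies each reference-channel
molecule against the three-channel CDC into both/first-only/second-only/
neither, for every choice of reference channel.

Under localization jitter the nearest-neighbour distance of a pair at
true separation d follows a Rice distribution, whose mode sits slightly
above d once the relative jitter σ√2 approaches d. At 20 nm precision
(jitter FWHM 10 nm per channel) the continuous mode for d = 6.8 nm is
≈ 8.5 nm and for d = 10.2 nm ≈ 11.6 nm. The binned mode therefore
typically recovers these separations in the bin adjacent to the true
one; this is a property of the noise model, not of the estimator.

## RDF and Ripley statistics

Point-based estimators via k-d-tree counts (exact, grid-free):

* G(r): observed target count in the annulus [rᵢ₋₁, rᵢ) around all
  source molecules divided by the expectation under uniform target
  density over the region; input radii act as annulus edges (0
  prepended) and the curve is indexed by annulus midpoints.
* K(r) = area/(n_s·n_t) · Σ_source #{targets within r}; L = √(K/π),
  H = L − r in 2-D (sphere counts and L = (3K/4π)^⅓ in 3-D, which is
  implemented but less exercised than the 2-D surface). H′ by central
  differences, one-sided at the grid ends.

No edge correction is applied by default; radii default to 10–1000 nm in
10 nm steps and a warning fires beyond half the region extent, where
border deficits dominate. For synthetic scenes on rectangular regions a
toroidal option wraps distances, making the CSR references exact
(G ≡ 1, K = πr², H = 0); the CSR property tests use it. A raster-parity
path (`raster_occupied_points`) maps a table to occupied 20 nm pixel
centres for comparison with raster-based pipelines.

Cluster radius from H: Lagache's estimate is argmax_r H(r) / 1.3, which
requires a strict interior maximum. Kiskowski's rule takes half the
radius where H′(r) first descends to −1. Because K is a cumulative count
and hence non-decreasing, H′ ≥ −1 pointwise, so "crossing −1" can only
mean the slope *reaching* −1 where K becomes locally flat — which
happens at r ≈ 2R for clusters that are well separated and sit on little
background. On dense multi-cluster fields with noise the slope bottoms
out above −1 (observed ≈ −0.85 on 50-cluster scenes) and the estimator
raises a no-crossing error rather than guessing; r_max/1.3 remains
applicable there. Both estimators are exposed so either convention can
be reported.

`h_segment` computes a Getis–Franklin-style local H at a fixed radius
per molecule, interpolates it to a raster and thresholds it into
8-connected components. The result depends strongly on the chosen radius
and threshold — it is retained for comparability, with OPTICS preferred
for unbiased segmentation.

## DBSCAN and OPTICS

DBSCAN counts the molecule itself in its ε-neighbourhood (|N_ε(p)| ≥ k
makes p core), matching the scikit-learn `min_samples` convention; the
test suite verifies exact partition equality against scikit-learn on
random fixtures. Clusters grow depth-first from unvisited cores in
ascending index order, making edge-point assignment deterministic.

OPTICS is implemented in its canonical priority-queue form: core
distance = distance to the k-th closest molecule counting itself
(k = `min_cluster_size`, default 0.5% of molecules with a floor of 5),
reachability RD(q) = max(core_distance(p), d(p, q)) minimized over
processed expanders, next point = smallest tentative RD with ties to the
lowest index. No ε cap is applied. The simplified "distance to the next
molecule in the list" description sometimes given for RD is *not* what
the canonical algorithm computes; the implementation follows the
canonical definition, which the brute-force oracle and scikit-learn
cross-checks pin down exactly.

Static-RD extraction labels maximal runs of ordered points with
RD ≤ threshold as clusters; a bounding peak whose own core distance is
≤ threshold seeds the following valley (this is what makes extraction at
threshold = ε reproduce DBSCAN up to edge assignment). Runs below
`min_cluster_size` are noise. A static threshold presumes homogeneous
cluster density.

Hierarchical RD segmentation splits each segment at its highest interior
peak (the peak joins no child). A child is retained when it has ≥
`min_cluster_size` molecules and mean RD ≤ `split_significance` × the
peak RD (default 0.75 — a segment whose mean approaches its bounding
peak is not a separate feature); retained children are segmented
recursively, failing children stay in the tree as discarded nodes, and
peaks are tried in descending order until a split retains at least one
child. Requiring *both* children to pass was tried and under-segments
badly: high-RD noise points interleaved in the ordering inflate one
child's mean and veto genuine splits. The segment's first position is
excluded from its statistics because its RD describes entry from outside
the segment. Reported clusters are the non-discarded leaves; parent
links preserve the nesting (vesicle-in-body structure). Clusters whose
RMS radius is at or below the localization precision can be flagged
(`flag_subresolution_clusters`) as likely repeat-detection artefacts.

Cluster composition across channels: convex hull of the cluster's
molecules (edge molecules for DBSCAN, per the standard workflow; an
all-points hull is a caller choice), boundary-inclusive containment
count of the other channel, density = count/area. The convex hull is
used as the "minimum bounding polygon" because it is parameter-free and
deterministic; an alpha-shape refinement is an extension point.

## Synthetic generators

All generators take an explicit seed and are bit-reproducible.

* **Pair fields**: n source molecules uniform in a square, partners at
  exactly the requested separation in a uniform random direction,
  optional unpaired excess in the second channel. Default extent 8500 nm
  at 5000 pairs gives ~60 nm same-channel spacing, the regime of
  sparsely deposited oligo fields. Localization error: isotropic normal
  jitter with FWHM = 0.5 × precision (σ = FWHM/2√(2 ln 2) ≈ precision/4.7).
* **Clustered fields**: cluster centres uniform; per-cluster molecule
  count = (mean + half-range) − U{0..2·half-range} and radius =
  (mean + half-range) − U[0, 2·half-range] (a Gaussian ± option exists);
  molecules placed by uniform random angle and uniform random radius,
  hence denser toward cluster centres; noise molecules (fraction of the
  clustered count, default 10%) uniform. Defaults model the acquisition
  study: 5000×5000 nm, 200 clusters of 100 ± 10 molecules, radii
  75 ± 37.5 nm. The co-clustering variant (50 clusters, fixed 50 nm
  radius, 100 molecules, two channels sharing the same clusters) drives
  the radius-estimator studies.
* **Sampling artefacts**: undersampling deletes a random fraction of
  molecules plus all same-channel molecules within the CDC of each
  (their putative repeat detections); oversampling duplicates a random
  fraction with positions redrawn uniformly within a disc of diameter
  21.27 nm (the typical two-colour CDC) centred on the parent.
* **Acquisition simulation**: per frame, a uniform random subset of
  10–20 molecules is "active" and each detection is jittered as above;
  10,000 frames at 20 nm precision by default, optionally after deleting
  10% of fluorophores to include undersampling.

What the generators do **not** emulate: fluorophore photophysics
(blinking kinetics, bleaching), camera noise, drift, chromatic
aberration beyond the scalar I_reg, z-dependent precision, and
non-circular cluster shapes. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated point
process, not robustness to every instrument artefact.

## Reconstruction stop-point

The acquisition is reconstructed cumulatively with a checkpoint every 50
frames; the autocorrelation at a checkpoint is the Pearson correlation
between the current and previous reconstructions. Two choices here are
genuinely open and were fixed as follows. The correlation is computed on
*binarized* rasters — occupied vs empty pixels — because the stop
criterion is about whether new frames still contribute new image
content; on count rasters the correlation is dominated by counts shared
between checkpoints and saturates almost immediately. The reconstruction
is rendered at 5 nm pixels (≈ a quarter of the nominal precision, the
usual render sampling for ~20 nm-precision data); the 20 nm raster
convention is kept for TIFF export and all Ripley/RDF rasters. The
stop-point is the first checkpoint with R > 0.990.

Reconstruction fidelity across checkpoints is scored on the binarized
20 nm raster representation: cross-Ripley H of the checkpoint's occupied
pixels against the ground-truth raster, compared with the ground truth's
own H through the peak height. Binarization is what makes oversampling
bite: repeat detections collapse onto already-occupied cluster pixels
while background keeps acquiring new ones, so the measured clustering
contrast decays past the ideal sampling point (exact point statistics
are, by the same token, insensitive to duplication — which is why
cross-RDF tolerates 25× oversampling). Peak height is used as the score
because the peak radius is grid-stable across checkpoints and a
full-curve RMSE has a shallow, noise-dominated optimum. In this
configuration the best-matching checkpoint's autocorrelation is ≈ 0.994
(mean over seeds) — computed by `scripts/acceptance.py`, not assumed.

## Problem sizes and runtime

The validation studies run at the generators' native scales: 5000-pair
fields for separation recovery, the full 200-cluster/10,000-frame
acquisition for the stop-point study (5 seeds), and ten 50-cluster
scenes for the radius-ratio study. The complete test suite and the
acceptance script each finish in about a minute on a single CPU; OPTICS
is O(n²) and comfortable for per-ROI molecule counts up to a few
thousand, with DBSCAN and all tree-based statistics scaling well beyond.

## Numerical conventions

Rasterization bins are half-open [i·s, (i+1)·s) anchored at the region's
minimum corner, with max-edge molecules assigned to the last pixel, so
pixel sums always equal molecule counts. Hull containment is
boundary-inclusive (facet inequalities with a 1e-9 slack). All
tie-breaks (histogram mode, OPTICS ordering, DBSCAN seeds) go to the
smaller value or lower index. Degenerate inputs — empty channels,
zero-area regions, collinear hulls, monotone H curves — raise typed
errors rather than returning silent defaults.
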