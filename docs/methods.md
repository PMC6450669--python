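# Methods

## Scope and data model

`mesotrack` quantifies single-cell migration and shape from manually
segmented 3-D time-lapse recordings of gastrulating mouse embryos. It
deliberately begins *after* segmentation and annotation: centroid tracks,
pair classifications (daughter / proximity / collision), label-mask
volumes and filopodium polylines are inputs, produced by an imaging
platform or by hand. Nothing in the package segments images, detects
mitoses or contacts, or renders video.

All coordinates are physical micrometres and all times are minutes from
the first frame; conversion from voxel indices happens at read time
using the configured voxel size. Defaults mirror the acquisition design
of the motivating experiments: frames every 20 min, 3 µm Z spacing
(voxel order Z, Y, X throughout). Tracks may have gaps — cells leave the
field — and every metric operates on the points actually present; no
frame is ever imputed. A track with a single point is carried through
readers and summaries but flagged (`note` column) rather than measured,
so no cell silently disappears.

## Trajectory metrics

For a track x(t₀)…x(t_N):

- net displacement `‖x(t_N) − x(t₀)‖`;
- travel displacement `Σ ‖x(tᵢ₊₁) − x(tᵢ)‖`;
- straightness = net / travel, in [0, 1]; a stationary cell (zero
  travel) reports *missing* rather than 0, since no direction was ever
  expressed;
- mean speed: the cumulative path-length curve is interpolated
  piecewise-linearly and differentiated; the duration-weighted mean of
  the resulting instantaneous speeds is reported. Under this
  interpolation the estimate collapses exactly to travel displacement
  over total duration. We keep the duration-weighted formulation (and
  test the identity to 1e-12 relative) rather than hiding it, because
  it states explicitly how sampling gaps are weighted: by the time they
  span.

Cohort statistics average per cell first — group mean straightness is
the mean of per-cell ratios, not the ratio of group means. The two
differ materially for tortuous populations.

## Drift correction

Cultured embryos translate slowly in their wells. The correction model
is a per-frame translation anchored at frame 0, estimated as the
displacement of a reference trajectory (the embryo-contour centroid):
offset(t) = ref(t) − ref(t₀); corrected positions are p − offset(t).
This is a deliberate simplification of full contour registration,
justified because residual embryo movement and growth are small relative
to cell displacement in usable recordings. Rotation is never estimated —
re-orientation of an embryo is a manual judgement — but user-supplied
per-frame rotation matrices are applied about the reference anchor when
given. Translation-only correction exactly preserves all inter-cell
distances; this invariance and exact cancellation of injected drift are
asserted in the tests to 1e-9 µm.

## Pair coupling

Each annotated pair is summarized over its tracking window by: the angle
between the two whole-window net-displacement vectors (one angle per
pair, arccos of the normalized dot product, clamped to [0, 180]°); the
net and travel displacement ratios, taken min/max so they are symmetric
in the two cells and lie in (0, 1]; and the mean and final Euclidean
inter-centroid distance over common timepoints. Common timepoints are
matched by exact equality — both cells come from the same stack grid —
with no temporal interpolation. The min/max ratio convention is a
documented choice: it is label-free and matches the "similar distance"
reading of a symmetric ≤ 1 ratio. Travel-displacement ratio is min/max
of travel displacements specifically, not of straightness.

## Morphometry

- **Volume**: occupied-voxel count × voxel volume. First-order unbiased
  for smooth shapes sampled at voxel centres.
- **Surface**: triangulated level-0.5 isosurface (marching cubes with
  anisotropic spacing). The binary mask is pre-smoothed with a Gaussian
  of one minimal voxel edge (per-axis sigma scaled by voxel size):
  meshing the raw binary field places vertices at edge midpoints and
  overestimates curved surfaces by ~8%, while the smoothed field is
  accurate to well under 1% on a 10 µm sphere at 0.5 µm voxels. The
  trade-off is at sharp edges: a rasterized cube loses ~4% to rounded
  corners (documented mesh tolerance 5% for edged phantoms). Masks
  thinner than 2 voxels along any axis cannot be meshed and fall back to
  exposed voxel-face area, so a single (1 µm)³ voxel reports 6 µm².
- **Cell stretch**: the mask is projected along Z (the imaging axis, the
  same convention used for filopodia quantification) and the ellipse
  with identical second central moments is fitted to the binary
  projection; the long/short axis ratio is reported. Each pixel
  contributes as a square (adds h²/12 per axis to the central moments),
  which makes an n×m-pixel rectangle yield exactly n/m and keeps the
  estimator within 2% on a 2:1 ellipsoid projection at 0.5 µm pixels.
  The underlying commercial "inner ellipse" feature is unpublished, so
  absolute stretch values are comparable only within this convention;
  relative comparisons between groups are what the measure is for.
  Collinear projections (all pixels on a line) are rejected.
- **Filopodia**: polyline arc length per filopodium and mean count per
  cell per timepoint, optionally split by target germ layer (epiblast
  vs visceral endoderm). Timepoints with zero traces count as zero only
  when the caller supplies the annotated-timepoint list — absence of a
  trace is otherwise indistinguishable from absence of annotation.

## Group statistics

The comparison procedure mirrors common practice in the field: test each
sample for normality (Shapiro–Wilk, α = 0.05; the gate's own false
rejection rate is checked by simulation), and use Welch's unpaired
two-sided t-test when both pass, the two-sided Mann–Whitney–Wilcoxon
otherwise. The t-test is Welch rather than Student because equal
variances cannot be assumed between cell populations of different size
and character. Mann–Whitney p-values are exact for combined n ≤ 12
without ties and use the normal approximation with tie and continuity
correction above that. All results carry n, mean and SEM (sd/√n) per
group and the test actually used, so reported tables are
self-describing. A from-first-principles enumeration oracle
(`exact_mww_p`) provides an independent check; the main path agrees with
it on every tie-free rank configuration with combined n ≤ 10. The
gate-then-test procedure's type-I error stays ≤ 0.07 at nominal 0.05
under Gaussian and exponential nulls (2000-rep simulation, fixed seed).
Zero-variance samples fail the gate by definition. No multiple-testing
correction is applied; the per-metric comparisons are reported raw.

## Synthetic generator

The simulator exists to make every stage testable with known ground
truth, not to model mesoderm biophysics. Cells follow a persistent
random walk on the unit sphere: each step's heading is a von
Mises–Fisher draw centred on the previous heading with concentration κ
(κ = 0: uncorrelated walk; κ → ∞: straight line), and step lengths are
speed × dt with lognormal speeds (positivity) of given mean and CV.
Heading concentration was preferred over an Ornstein–Uhlenbeck velocity
process as the minimal parameterization that spans the observed regimes
and gives clean monotonicity targets (straightness increases with κ).

Default conditions mirror the tracked cohorts: dt = 20 min, 8 steps
(~160 min of track against the experiment's ~150), 34 embryonic cells at
0.67 µm/min and 17 extra-embryonic cells at 0.44 µm/min (the measured
group means), speed CV 0.3. κ has no measured counterpart — the study
fits no motion model — so values were fixed once from the qualitative
regimes: κ = 5 for "meandrous but directional" embryonic motion and
κ = 0.3 for extra-embryonic motion with no obvious directionality.
Daughter pairs share a start position and a common base-heading chain;
each sibling's realized heading is an extra vMF draw around the base
with concentration `pair_jitter`, so the mean pair angle decreases
monotonically in the coupling strength. Ellipsoid phantoms are
rasterized at voxel centres on an (i + ½)h grid — the standard
pixel-centre convention, which avoids boundary-exact samples and halves
tip-pixel moment bias. Filopodium counts are Poisson per cell per
timepoint with polylines of controlled arc length. Every generator is a
pure function of its seed.

What the generator does **not** emulate: tumbling/run alternation within
single tracks (persistence is constant per cell), cell divisions
mid-track, segmentation noise on centroids, anisotropic localization
error, spatially structured guidance fields, or contact interactions.
Passing tests therefore demonstrate that the measurement pipeline is
correct and sensitive under the stated cohort geometry — not that real
mesoderm follows a vMF persistent random walk.

## Numerical conventions and problem sizes

- Exact assertions where mathematics is exact (net ≤ travel; straight
  line straightness = 1; drift cancellation), 1e-9–1e-12 relative
  tolerances for floating-point identities, and discretization-bound
  tolerances (2–5%) for voxel phantoms at 0.5 µm.
- Monte Carlo checks use fixed seeds and modest sizes chosen for a
  laptop-friendly suite: 200 cells per κ level for monotonicity, 200
  replicates for the two-region power check (34 vs 17 cells), 2000
  replicates for type-I error, 500 cells for Poisson count recovery.
- CSV floats are written via the shortest round-trip representation and
  parsed with round-trip precision, so write∘read is bit-exact and
  repeated writes are byte-identical; all report TSVs are emitted in
  deterministic order.

## Known limitations

- Absolute surface area and stretch carry the conventions above; when
  comparing against values produced by other software, expect a
  convention offset (e.g. voxel-face surface areas run ~8–50% higher on
  curved shapes) and compare within one convention.
- The drift model is translation-first; recordings with substantial
  embryo rotation require externally supplied rotation matrices.
- Pair metrics require both cells on a shared timepoint grid; tracks
  resampled at different cadences are not interpolated.
- The exact Mann–Whitney oracle is restricted to tie-free samples with
  combined n ≤ 12 by construction; it is a verification tool, not the
  production path.
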