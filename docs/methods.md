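# Methods

This note documents the models, conventions and design choices behind
`snowmorph`, in the order the pipeline runs.

## Vignettes and descriptors

A vignette is a single-particle 8-bit greyscale image (0 = black,
255 = white) with a pixel size in mm; UVP-class instruments store such
cut-outs for objects larger than ~80 px. Synthetic vignettes are
re-segmented by thresholding (foreground = pixels darker than the
threshold, default 245) and keeping the largest 8-connected component;
field vignettes are already segmented, so the threshold only needs to
separate object from white background.

The 24 descriptors span four groups — size, grey intensity, shape,
structure. The exact formulas follow standard particle-imaging
conventions and are chosen to be *exactly* checkable against
brute-force pixel counting:

* **Perimeter** is the count of foreground pixel edges adjacent to
  background (or the image frame). This is an exact combinatorial
  quantity, unlike Crofton-type estimators. A consequence worth
  knowing: the edge-count perimeter of a digital disc tends to 8r, so
  the circularity 4πA/P² of discs increases with radius toward
  π²/16 ≈ 0.62, not toward 1. Circularity can also slightly exceed 1
  for some small digitized shapes; values are reported uncapped.
* **Axes and elongation** come from the second central moments of the
  pixel coordinates with the +1/12 pixel-extent correction (each pixel
  treated as a unit square). Under this convention a 1×n bar has
  elongation exactly n and a single pixel exactly 1, with no special
  cases.
* **Grey statistics** (mean, median, min, max, integrated, st.dev.,
  skewness, kurtosis, range) are computed over foreground pixels only;
  background never contributes. Skewness and excess kurtosis use
  population moments and return 0 for zero-variance objects.
  *Darkness* is 255 − mean grey, so dark particles score high.
* **Boundary index** is ln(1+P)/ln(1+A): a compactness/ramification
  measure that stays finite for single-pixel objects (the plain
  log P/log A form is undefined at A = 1).
* **Axis symmetries** are the fraction of foreground pixels whose
  mirror image about the major (resp. minor) inertia axis through the
  centroid is also foreground.

Note that two descriptors are exact linear functions of others
(darkness of mean grey; grey range of min and max grey). This is
intentional — the descriptor list mirrors what particle-imaging
pipelines export — but it makes the correlation matrix rank ≤ 22, so
PCA components beyond the numerical rank are unavailable (an error
lists the collinear variables if requested).

## Trimming, transformation, PCA

Outliers are removed by trimming, per descriptor, values outside the
empirical [f/2, 1 − f/2] quantile interval (default f = 0.001, i.e.
the 0.1 % most extreme values); an object extreme in *any* descriptor
is dropped (union), because a truncated vignette or segmentation
artefact corrupts the whole record. Quantiles use order statistics
(`method="lower"/"higher"`), so the bounds are attainable data values
and a fraction too small to single out any row drops nothing; trimming
that would remove more than 20 % of rows raises, signalling a
pathological table. The bounds are stored: objects projected later
through a fitted morphospace are never dropped, only flagged when
outside them.

The right-skewed size/structure descriptors (area, perimeter, ESD,
convex area, integrated grey, perimeter/area) are mapped through
log10(1+x); all descriptors are then standardized (population st.dev.)
with constants learned at fit time and reused verbatim at projection
time. PCA is computed as the eigendecomposition of the resulting
correlation matrix — descriptors have incommensurate units, so
correlation (not covariance) PCA is the only defensible choice — and
the default 4 components are retained. Signs are fixed so each
component's largest-magnitude loading is positive, making fits
identical across runs and platforms; scikit-learn's PCA serves as an
independent cross-check in the tests. On the synthetic population the
first 4 components carry ~87–88 % of the variance.

## Clustering, naming, agreement

k-means (scikit-learn, k-means++ initialisation, best of 10 restarts,
seed required) partitions the 4-D coordinates into k = 5 morphotypes.
Assignment is nearest-centroid with exact ties broken toward the
lowest centroid index. Cluster indices are arbitrary, so before any
two classifications are compared their labels are aligned by optimal
assignment (Hungarian algorithm) on the confusion matrix; percent
agreement and unweighted Cohen's κ = (p_o − p_e)/(1 − p_e) are then
reported. When both labelings are constant and equal, p_e = 1 and κ is
reported as 1 with a `degenerate` flag.

Cluster names are a deterministic codification of the field
morphotypes' median signatures, applied in consuming order: largest
median perimeter → *agglomerated*; then highest darkness → *dark*;
then highest elongation → *elongated*; of the remaining two, higher
grey st.dev. → *fluffy*, the other → *flake*. The order guarantees a
bijection; it is a documented heuristic, valid when the five clusters
actually correspond to these morphotypes (k ≠ 5 falls back to generic
names with a warning).

## Concentrations and export metrics

Concentrations are counts divided by sampled volume in half-open 5-m
depth bins [z, z+5), per cast, time and morphotype (the study-scale
average volume is ~112 L per bin); sampled-but-empty bins are zeros,
unsampled bins are absent, and an object in an unsampled bin is an
error. Depths are metres, positive downward.

* **Size spectrum**: particles are counted in log-spaced ESD bins
  (5 per octave by default); the normalized abundance
  n = count/(volume × bin width) is fitted by OLS as
  ln n = ln a + b ln d over non-empty bins, d the geometric bin centre.
  At least 3 non-empty bins are required.
* **Attenuation**: for one morphotype profile, OLS of ln n(z) on
  ln(z/100) over bins with positive concentration in (0, 500] m yields
  the exponent b (negative = concentration decreasing with depth) and
  n₁₀₀ = exp(intercept). Both parameters are free; at least 3 usable
  bins are required.
* **Diversity**: Shannon–Wiener H = −Σ pᵢ ln pᵢ over morphotype
  concentrations (natural log; bounded by ln k). A sensitivity routine
  refits k-means at k = 25/50/100 and reports the Spearman rank
  correlation of the per-stratum diversity ordering against the k = 5
  baseline.
* **Sinking rates**: the depth of the maximum-concentration bin is
  tracked through time (bin centres, ties toward the shallowest bin,
  optional 3-bin smoothing, all-zero profiles omitted); a type-I (OLS)
  regression of peak *time* on peak *depth* gives a slope in d m⁻¹
  whose inverse is the bulk sinking speed in m d⁻¹. Non-positive
  slopes return a non-sinking flag instead of a speed. A separate
  helper computes the upper-bound speed depth/elapsed (e.g. 900 m in
  10 d → 90 m d⁻¹).

"Type I" is read as ordinary least squares (not major-axis/type II).
Peak depths are not interpolated below bin resolution — this keeps the
estimator exactly checkable — so a noiseless deepening peak is
recovered *exactly* only when observation times coincide with the peak
crossing bin centres; otherwise recovery is exact to within the ±2.5 m
quantization, which the regression averages out over several time
points.

## Synthetic data

The generator produces the five archetypes as parameterized shapes:
dark and flake are filled discs (dark very dark and slightly larger;
flake bright and smooth), elongated a randomly oriented high-aspect
ellipse (aspect 4–6.5), fluffy a thresholded smoothed-noise blob with
a rough boundary and strong structured grey texture, agglomerated a
chain of 4–8 overlapping discs with per-blob shades (guaranteeing one
connected component). Size scales are lognormal. The default
parameters were tuned once against the qualitative median ordering of
the field morphotypes — dark darkest, elongated highest aspect,
agglomerated largest perimeter, flake small/bright/smooth, fluffy
medium/heterogeneous, median perimeters flake < dark < fluffy ≈
elongated ≪ agglomerated — and then frozen; tests target the ordering
and cluster separation, not absolute pixel values.

Concentration fields superpose a Gaussian peak of configurable
amplitude and width, centred at z = v(t − t₀) for sinking speed v, on
a Martin background n₁₀₀(z/100)^b, one cast per time point, every 5-m
bin sampled at 112 L by default. Observations are either exact
expected concentrations at bin centres ("noiseless") or Poisson counts
with mean volume × n(z,t), expanded to per-object records at bin
centres. Truth (v, b) is returned for recovery tests.

What the generator does *not* emulate: optical blur and light-sheet
vignetting, particle overlap/occlusion, the living/non-living
continuum, depth- or time-varying archetype morphology, overdispersed
counts (a Poisson observation model is assumed), and advection.
Passing recovery tests therefore demonstrates the correctness and
stability of the pipeline under its own assumptions, not field-data
performance.

One subtlety in the diversity-sensitivity test design: for large k,
the per-stratum cluster-occupancy diversity converges to
ln k − KL(stratum composition ‖ pooled composition), so a set of
phases with increasing evenness can still invert its ordering at
k = 25–100 if the phases load very unequally on the mixture
components. The synthetic phases are therefore designed with equal
pooled mass per component, which makes the large-k ordering coincide
with the designed evenness ordering — mirroring the robustness of the
phase-diversity conclusions to the choice of k.

## Problem sizes and tolerances

Default test/verification scales, chosen to keep the suite fast while
leaving comfortable statistical margins: 2000-vignette populations for
end-to-end recovery (≥95 % required; typical results are ≥99 %);
100 000 draws for spectrum-slope recovery (±0.1); 112 L Poisson
sampling over 50–500 m for attenuation recovery (±0.1); peak tracking
over ~10 time points for sinking-speed recovery (exact noiseless at
bin-centre-aligned times, ±10 % under Poisson noise). Numerical
tolerances: orthonormality and closed-form eigenvalues at 1e-9;
standardization at 1e-9; full-rank reconstruction at 1e-6; PCA rank
tolerance 1e-10 relative to the leading eigenvalue.

## Known limitations

* The 24-descriptor list is a standard-convention set spanning the
  four stated groups; other imaging pipelines export variants (e.g.
  Feret diameters, grey-level co-occurrence features) that are not
  included.
* The naming rules assume the five clusters correspond to the five
  canonical morphotypes; on data with a different structure they will
  still produce names, which should then be treated as suggestions.
* Grey statistics are computed over the object mask; pipelines that
  include a background annulus will produce systematically different
  structure descriptors.
* The attenuation fit uses all positive bins in (0, 500] m and does
  not exclude the surface mixed layer.
* Fluxes in mass units are out of scope: converting concentrations to
  flux requires particle density and porosity, which images alone do
  not constrain.
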