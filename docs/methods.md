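# Methods

## The measurement model

Each accepted neuron's readout on a channel is its background-subtracted
integrated pixel intensity normalized by cell area and exposure time,

    I = Σ_mask (pixel − bg) / (A · t · g),

with `A` the mask area in μm², `t` the exposure in seconds and `g` an
optional camera gain (counts per intensity·μm²·s). Normalizing by area
makes cells of different sizes comparable; normalizing by exposure makes
images taken at different auto-selected exposures comparable (verified to
quantization tolerance by the exposure-invariance tests). Intensities are
finally rescaled so the control condition's mean is exactly 1, which puts
all conditions on a common "fold of control" scale.

Exposure is auto-selected per scene as the longest of a descending
candidate list (default 0.96, 0.48, 0.24 s) for which the number of
saturated pixels per 100 μm² of evaluated area stays within a budget
(default 1000). The reference area is ambiguous in common usage — per
object or per field — so both readings are available: pass an object mask
to evaluate per object, or omit it to evaluate the whole field. If no
candidate satisfies the budget the shortest is used with a warning.

## Object identifier

Connected components of pixels exceeding the image-wide background mode by
≥ 30% are measured and filtered by:

- **area** 150–1500 μm² (equivalent diameter ≈ 13.8–43.7 μm);
- **aspect ratio** = longest / shortest caliper (Feret) diameter ≤ 2,
  computed by rotating calipers over the convex hull of the pixel corner
  points (matching "ratio of longest to shortest diameter", not fitted
  ellipse axes). Rasterization inflates a digital disc's corner-point
  aspect by a few percent, far from the threshold;
- **concavity depth** ≤ 0.25, defined as the maximum distance from any
  point of the convex-hull deficiency to the object, divided by the
  equivalent *radius*. The radius normalization makes the threshold
  scale-free and puts the canonical failure case — a dumbbell of two
  touching 20-μm somata, depth ≈ 0.29 — above the 0.25 threshold, which a
  diameter normalization (0.146) would not;
- **contrast**: mean object intensity at least 30% above the local
  background, estimated as the median of a 10-μm annulus around the object
  excluding all detected objects (fallback: image-wide mode);
- **border**: any mask pixel in the first/last row or column rejects the
  object (0-based, row-major pixel convention);
- **cluster**: a component whose distance transform has ≥ 2 peaks separated
  by more than half the minimum accepted diameter, or that merges with
  another above-minimum-size component when every object is dilated by
  1 px. Clusters are rejected, not split: clustered neurons behave
  differently from singlets, so watershed recovery would bias the biology.

Every object is annotated with *all* failed rules; loosening any single
threshold can only grow the accepted set (a tested monotonicity property).

## Histogram-intersection classification

Positive/negative (and responder/non-responder) cutoffs are density
crossings between a reference and a test condition on shared bin edges
(pooled 0.1–99.9 percentile range, 100 bins). Because immunofluorescence
intensities are lognormal-like, crossing detection runs on log-intensity
histograms: density crossings are invariant under monotone transforms
(both densities acquire the same Jacobian), and the log scale resolves the
crowded low-intensity region where linear bins fail. Densities are
smoothed with a Gaussian kernel (Silverman bandwidth) before crossing
detection; raw densities are retained.

The cutoff is the first crossing at or right of the reference-density mode
where the test density stays above the reference for ≥ 3 consecutive bins.
Two guards handle degenerate geometry: if the test density exceeds the
reference everywhere, the cutoff drops to the pooled minimum ("complete
shift", e.g. a phorbol-ester stimulation that activates every neuron); if
no sustained crossing exists, or the excess fraction above the cutoff
(test − reference) is smaller than twice its binomial standard error, the
result is "no responders" with fraction 0 — this suppresses the spurious
crossings that finite samples of identical distributions otherwise
produce. Ties at the cutoff classify negative, keeping the estimate
conservative with respect to true positives.

Subgroup fractions are reported per culture when culture ids are present,
with the across-culture SD as the spread (the natural reading of a
"±" on a fraction of biological replicates); the across-cell SEM is also
available. Subgroup profiles use 2-μm diameter bins and one-tailed
unpaired t-tests on channel means; time-course/dose summaries report
n, mean and SEM per group with no interpolation or fitting.

## Virtual wells

The sensitivity of a culture-mean readout is estimated by resampling
"virtual wells" of *n* cells from the pool of all *N* measured cells
(default 10,000 wells) and taking the SD of the well means. Sampling is
**without replacement** by default: a virtual well is a subset of distinct
measured cells, and the resulting SDs follow the finite-population-
corrected closed form `σ/√n · √((N−n)/(N−1))` to within Monte-Carlo noise
at every well size, which the with-replacement form (`σ/√n`) misses by up
to ~20% once n approaches N/2. Both modes are implemented. Without-
replacement subsets are drawn by the random-keys method (the n smallest of
N iid uniform keys index a uniform n-subset), vectorized with
`argpartition` in chunks.

The minimal detectable whole-culture change is `k · SD` of the well mean
as a percent of the mean (`k = 2` default); a change confined to a
subgroup of fraction *f* must be `1/f` times larger within the subgroup.
The headline arithmetic rounds the SD percent first (11% → 22% → 110% at
one fifth), and the calculator reports unrounded values alongside.

## Synthetic cultures

The generator emulates the statistical structure of dissociated adult-rat
DRG cultures; its defaults are the study conditions all tests run under:

| parameter | default | meaning |
|---|---|---|
| `baseline_mean`, `baseline_cv` | 1.0, 1.80 | lognormal baseline phospho-signal on the control-mean scale; CV 180% |
| `ib4_positive_fraction` | 0.71 | bimodal IB4 mixture weight |
| `ib4_neg_mean/cv`, `ib4_pos_mean/cv` | 0.15/0.40, 2.0/0.90 | unspecific-binding and specific IB4 lognormal components; the low component doubles as the blocked control |
| `responder_fraction`, `responder_fold_change` | 0.50, 10 | multiplicative response on baseline, × lognormal noise (`response_noise_cv` = 0.10) |
| `diameter_range_pos/neg` | 22–32 / 14–24 μm | uniform soma diameters per IB4 class |
| `cluster_fraction`, `border_fraction` | 0.16, 0.03 | placement classes per cell |
| `glia_density`, `debris_density` | 3, 5 per field | distractor objects |

Intensities are lognormal parameterized by arithmetic mean `m` and CV `c`
(`σ² = ln(1+c²)`, `μ = ln m − σ²/2`) — the standard non-negative
heavy-tailed choice consistent with an observed ~100-fold intensity
spread. Responses are multiplicative fold changes, preserving
non-negativity. Where a quantity is unavoidably free — the IB4 component
locations, the response noise CV, the pixel size (0.645 μm/px at 10×), the
camera gain — values were chosen once as typical for this kind of assay
and are configurable.

Rendering places singlets on a jittered grid, clustered cells as touching
pairs and border cells cut by the field edge (1280 × 1024 px), draws each
neuron as a near-circular ellipse (aspect ≤ 1.3) of uniform surface
brightness so that noise-free quantification returns the true intensity
exactly, adds Gaussian read noise and quantizes to 12 bits with hard
clipping at 4095. Glia render as low-contrast blobs or bright crescents
(violating the contrast or concavity rule), debris as sub-150-μm² specks.
The renderer deliberately omits point-spread-function optics,
photobleaching, illumination gradients, intensity-graded cell borders and
3-D structure, so passing tests demonstrate the correctness of the rules
and estimators on cells that *satisfy the model's geometry* — they do not
certify segmentation accuracy on real micrographs with soft edges or
out-of-focus neurites.

### Reference intensity pool

The virtual-well analysis uses a 49,503-cell pool specified by its sample
moments (mean 1.0, SD 1.80). A raw lognormal draw of that size carries
~5% sampling error in its SD (the law's excess kurtosis is ≈ 520), which
would propagate verbatim into every well SD, so
`baseline_intensity_population` rescales the draw affinely to the exact
target moments and clamps at zero (relative effect on the moments
< 1e-4).

## Problem sizes and numerical choices

The test suite and the acceptance script use the study-condition sizes
directly where they are cheap (49,503-cell pool, 10,000 wells per size,
40,000-cell IB4 scenarios, 4,000-cell stimulation scenarios, 10 seeds per
recovery estimate) and a ~650-cell rendered fixture set (≥ 500 eligible
singlet neurons across several full-size fields) for segmentation recall.
Monte-Carlo assertions use 3 × the analytic Monte-Carlo SE of the
estimator in question; exact arithmetic is asserted to 1e-9 or tighter.
Seeds are fixed everywhere; identical configuration and seed give
bit-identical populations, images and resampling draws.

## Known limitations

- The object identifier assumes sphere-like somata; it is not a general
  cell segmenter and makes no attempt at neurite tracing or cluster
  splitting.
- The intersection cutoff is undefined in principle when the responding
  and reference distributions coincide; the significance guard then
  reports zero responders rather than a noise-driven fraction.
- Per-culture spreads require culture ids; with pooled cells only the
  across-cell SEM is available.
- The camera model quantizes uniformly; per-cell rounding bias of up to
  0.5 count/pixel bounds the agreement between exposures (the documented
  quantization tolerance).
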