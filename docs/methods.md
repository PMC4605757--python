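# Methods

## The model

A multispectral cube is an `m × n × W` stack of reflectance images of one
scene, band axis last, wavelengths strictly increasing (default: 18 bands,
405–970 nm). The segmentation model assumes the scene is a small number of
spectrally near-homogeneous regions (background, dish, sample, optionally
fat), observed through

* a per-pixel multiplicative illumination gain, constant across bands, and
* additive, band-independent Gaussian sensor noise.

The pipeline never classifies spectra directly. It reduces the cube to a
single grey image (one band-pair difference), and reduces segmentation to
1-D histogram thresholding — the two reductions are where all the design
decisions live.

## Normalization

Phase one rescales every band to [0, 1] by its own min and max. Constant
bands map to zeros and are flagged rather than raising, so a dead channel
cannot abort a batch. Phase two (SNV) centers and scales each pixel
spectrum, using the sample (W−1) standard deviation — the paper-style
formula does not fix the denominator and any consistent choice preserves
the invariance `snv(a·v + b) = snv(v)`, a > 0, which is what removes the
multiplicative gain. Spectra whose standard deviation is at roundoff level
(≤ 1e-12 relative) are treated as constant and zeroed, not amplified.

Band selection operates on the phase-one (band-normalized) representation,
not on SNV output: the contrast measure needs nonnegative grey levels and
SNV values are signed. The SNV cube is retained for spectral export.

## Band-pair selection

For each of the C(W, 2) unordered pairs the difference image
`|b_i − b_j|` is min-max rescaled to [0, 1] and scored by the edge-based
contrast measure; the pair with the minimum score wins, ties broken
lexicographically. Numerical conventions:

* Sobel magnitudes and the 3×3 neighborhood sums use mirror padding (the
  edge pixel not repeated, numpy's `pad(mode="reflect")`), so all `m·n`
  pixels enter the average.
* A neighborhood with zero total edge weight takes `e = I`, hence zero
  local contrast; pixels with `I + e = 0` contribute 0 (the limit along
  `I = e`). Both conventions keep the score within [0, 1] and make a
  constant image score exactly 0.
* A constant difference image (duplicate bands) is defined as all-zero
  after rescale, scores 0, and therefore wins outright; if *every*
  candidate is constant the cube has no contrast and the stage raises.
* In the masked variant (stage 2) the rescale and the average use only
  pixels inside the mask; the rescaled image is clipped to [0, 1] so that
  out-of-mask pixels cannot push the neighborhood sums outside the nominal
  grey range.
* The combiner is pluggable (`difference` | `ratio`); absolute difference
  is the default and the only one exercised by the pipeline.

Rescaling before scoring is essential, not cosmetic: without it, a pair
whose regions happen to coincide (e.g. fat ≈ lean) yields a nearly
constant image with almost no edges and would always win, despite carrying
no contrast. Rescaling stretches such an image's noise to full range,
raising its score, so flat-but-separated plateau pairs win instead.

## Mixture thresholding

The winner's intensities are binned into a 256-bin histogram and fitted by
EM with C = 1 and C = 2 components (weighted/binned EM; a 1.4-megapixel
image fits in milliseconds and the result is independent of pixel order).
Initialization is deterministic — means at evenly spaced data quantiles,
equal weights, variances at the data variance — because reproducibility is
a design goal; there are no random restarts. Variances are floored at
1e-4 of the data variance to prevent component collapse on spiky
histograms. Constant data short-circuits to a flagged single-component
fit. Convergence: relative log-likelihood change below 1e-7 or 500
iterations; the per-iteration log-likelihood trace is stored and is
nondecreasing (EM guarantee, asserted in tests).

Model choice uses the minimum-message-length score

    ML = (N_p/2) Σ_m ln(n π_m / 12) + (C/2) ln(n/12) + C (N_p + 1)/2 − loglik

with `N_p = 2` parameters per 1-D Gaussian; zero-weight components are
excluded and do not count toward C. Only MML *scoring* of separately
fitted candidates is implemented — the full component-annihilation scheme
of the unsupervised-mixture literature is unnecessary for a 1-vs-2
decision.

**Bayes threshold (C = 2).** The crossover `π_1 N_1(t) = π_2 N_2(t)` is a
quadratic in t, solved in closed form; the root inside `[μ_1, μ_2]` is
taken (when both roots fall inside, the one nearer the midpoint). If no
root lies between the means — extreme weight/variance imbalance — a
10⁶-point grid search on the posterior difference is used instead. In the
regime where the weighted densities change order between the means the
interior crossover is unique and thresholding at it reproduces the MAP
classification there.

**Tail rejection (C = 1).** A Gaussian's kurtosis is a constant, so "the
larger tail" is identified by the sample skewness instead: positive
skewness rejects the upper tail at `μ + k·σ`, negative the lower at
`μ − k·σ` (k configurable, default 2.0 — about 2.3% of a Gaussian bulk);
skewness at roundoff level rejects nothing. The exact statistic and cutoff
are the package's own choice; k is exposed in `FitConfig`.

## The cascade and its two guards

Stage 1 (full image) removes the surround; stage 2 re-runs band selection
and thresholding using **only** pixels inside the stage-1 mask — without
that restriction the surround re-contaminates the fat/lean histogram. The
final mask is the conjunction, so it is always a subset of stage 1's. A
stage-2 failure (too few pixels, no remaining contrast) degrades to the
stage-1 mask with a logged warning. Which side of a threshold is "sample"
is not decidable from the histogram (fat can outweigh lean); the default
rule takes the side that dominates the central 25%-area window — samples
are centered in the dish — and is configurable
(`above | below | central | larger_component`). For the tail-rejection
path the non-rejected side is foreground by construction.

Two guards make the cascade robust on real (speckled) masks:

* **Small-object removal, default ON (min size 9 px).** Threshold
  classification errors in overlapping tails produce isolated stray
  pixels. Left in the stage-1 mask they do double damage downstream: they
  stretch the stage-2 masked rescale (so a contrast-free band pair can win
  the minimum-score race) and they form far-out satellite clusters in the
  stage-2 histogram. Nine pixels is well below any meaningful food region
  at the default scales; hole filling stays OFF so genuine fat "holes"
  are never filled in.
* **Two-population check.** MML answers a coding question — "is the
  histogram better described by two Gaussians?" — which is not the
  segmentation question. Heavy tails, or a 0.1%-weight cluster of stray
  pixels, can win the coding comparison while not being a class. A C = 2
  winner is therefore accepted for Bayes thresholding only when the
  mixture is actually bimodal (mean separation ≥ 2 in units of the larger
  component sd — the classical bimodality bound for an equal-variance
  mixture) *and* both classes cover ≥ 2% of the analyzed pixels; otherwise
  the stage refits C = 1 and takes the tail-rejection path. Both bounds
  are exposed in `PipelineConfig`.

## Phantom generator

`make_phantom` renders `gain(x,y) · signature_region(w) + ε`, clipped at
zero, with `ε ~ N(0, 0.02²)` and the gain drawn per pixel from a normal
centered on the midpoint of the gain interval (default [0.8, 1.2]) with
σ = width/8, truncated to the interval — illumination falloff concentrates
around its mean between hard physical bounds, and an iid *uniform* gain
would give within-region histograms a uniform shape no diffuse-illumination
acquisition has. The gain is constant across bands by construction: it is
precisely the multiplicative component SNV removes, which makes the
preprocessing claim testable.

Every preset scene contains a bright dish ellipse under the sample on a
dark background. This is not decoration: with only two spectrally distinct
regions, per-band min-max normalization maps both regions onto nearly the
same two levels in *every* band, all difference images collapse to noise,
and no band pair carries contrast — a genuine limitation of the
normalization-then-difference construction that real scenes escape because
they always contain more than one non-sample feature. The meat preset's
fat signature is chosen the way real fat behaves: similar to lean in the
blue↔NIR contrast (so fat stays with the sample through stage 1) but
distinct in the mid-visible bands (so stage 2 separates it).

Default scene size is 256×256 (desk-scale; full 1200×1200 generation is
supported but ~20× slower). What the phantoms do **not** model: texture
within regions, optical blur at boundaries, specular highlights, spatially
correlated noise. Passing the phantom suite therefore shows the pipeline
recovers the structure the method assumes; it does not show robustness to
every artifact of real meat surfaces.

## Evaluation statistics

Area fractions are mask counts over `m·n`. The regression report is
ordinary least squares `y = a·x + β` with R², RMSE, Pearson r and the
exact two-sided t-test p-value (n − 2 df). Colocalization percentages are
normalized by the basis mask's area (basis treated as ground truth), so
`coloc% + basis-exclusive% = 100` per sample; a symmetric Dice score is
reported alongside as a convenience. Aggregation over samples reports the
mean and the standard error (sample std / √n). Band summaries are
per-band mean and sample std over masked pixels, ignoring NaN.

## Problem sizes and determinism

The test suite and the acceptance script use 256×256×18 phantoms (the
method's behavior is scale-free above the histogram-resolution limit;
256² ≈ 65k pixels gives ~260 pixels per histogram bin). Everything is
deterministic given (data, config, seed): deterministic EM initialization,
lexicographic tie-breaks in band ranking, and seeded generators. Identical
runs produce bit-identical masks and reports across process restarts.
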