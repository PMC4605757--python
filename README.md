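# foodseg

Fully automated segmentation of multispectral food images.

Multispectral acquisition systems for food science (e.g. integrating-sphere
instruments recording 18 narrow bands between 405 and 970 nm) produce an
`m × n × W` reflectance cube per sample. Before any chemometric or
quality-prediction analysis, the *informative area* — the food sample
proper, excluding the dish, the packaging, and (for meat) fat and
connective tissue — has to be extracted. Doing that by hand, or with
supervised per-sample labeling, is slow and subjective. `foodseg`
implements an unsupervised two-stage pipeline that needs no labels and no
user interaction, so the same cube always yields the same mask.

## Method

1. **Normalization.** Each band image is min-max rescaled to [0, 1],
   `I'_w = (I_w − min I_w) / (max I_w − min I_w)`; in addition each pixel's
   spectrum is Standard-Normal-Variate transformed,
   `I_SNV = (I − mean I) / std I`, which cancels the per-pixel
   multiplicative illumination gain (kept for spectral export).
2. **Band-pair selection.** For every pair of bands *(i, j)* the
   difference image `I_diff = |b_i − b_j|` (rescaled to [0, 1]) is scored
   with the edge-based contrast measure

   `EBCM(I) = (1/MN) Σ_{x,y} |I − e| / |I + e|`,

   where `e(x, y)` is the Sobel-gradient-weighted mean grey level of the
   3×3 neighborhood. EBCM is large for edge-rich images and small for
   blurry, piecewise-flat ones; the pipeline keeps the pair with the
   **minimum** EBCM — the flattest difference image is the one whose
   regions separate most cleanly in the histogram.
3. **Mixture thresholding.** The winner's grey-level histogram is fitted
   with 1-D Gaussian mixtures, `f(y|Θ) = Σ_m π_m N(y; μ_m, σ²_m)`, by EM.
   The minimum message length (MML) criterion decides between one and two
   components. Two separated components give the Bayes-rule threshold (the
   intensity where `π_1 N_1(t) = π_2 N_2(t)` between the means); a single
   component gives a tail-rejection threshold `μ ± k·σ` on the heavier
   tail (sample skewness picks the side).
4. **Cascade.** Stage 1 runs on the whole image and removes the
   surround; stage 2 repeats band selection and thresholding *inside* the
   stage-1 mask and removes fat/connective tissue. The final mask
   (stage 1 ∧ stage 2) is applied to all bands (excluded pixels → NaN).

A seeded phantom generator (`foodseg.preset` / `foodseg.make_phantom`)
builds synthetic cubes with ground-truth masks for the three scene
archetypes (meat with fat speckles, homogeneous crème, scattered olives),
and the evaluation module provides the comparison statistics: informative
area fractions with OLS regression and Pearson correlation, binary
colocalization against a basis mask, and per-band mean ± std reflectance.

## Worked example

```sh
foodseg synth --preset meat --seed 0 --out demo/phantom
foodseg run demo/phantom/cube.tif --out demo/result
foodseg eval --pred demo/result/final_mask.png --basis demo/phantom/truth_sample.png
```

prints

```
wrote phantom 'meat' (seed 0) to demo/phantom
stage1 pair (1, 17), stage2 pair (6, 15); informative area 0.3257
wrote demo/result/final_mask.png
{
  "coloc_pct": 100.0,
  "excl_a_pct": 0.0,
  "excl_b_pct": 0.0,
  "dice": 1.0
}
```

Stage 1 picked bands (1, 17) — the 435 nm / 970 nm contrast that isolates
the sample-plus-fat region from dish and background — and stage 2 picked
(6, 15) (570 nm / 890 nm), where fat and lean separate. 32.6% of the
image is informative area, and the final mask covers the true lean region
exactly (colocalization 100%, Dice 1.0 against the generator's ground
truth; no area is exclusive to either mask). `demo/result/report.json`
holds the full EBCM rankings, the fitted mixtures and the thresholds.

The same calls work from Python:

```python
import foodseg as fs

truth = fs.make_phantom(fs.preset("meat", seed=0))
result = fs.run_pipeline(truth.cube)
print(result.stage1.pair, fs.dice(result.final_mask, truth.truth_sample))
```

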