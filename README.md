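# confmap — confidence maps for cryo-EM densities

Choosing an isosurface threshold for a cryo-EM density map is subjective:
recommended σ levels vary from structure to structure (and within one
structure), and after sharpening, weak high-resolution features sit close to
the noise floor, so any fixed σ contour either misses real signal or admits
noise. `confmap` replaces the σ contour with a statistically calibrated one.
It transforms a (sharpened) map into a **confidence map** whose voxel values
are positive predictive values (PPV): contouring the confidence map at 0.99
yields a binarisation in which at most 1% of the shown voxels are expected to
be background — a false discovery rate (FDR) of 1% — regardless of the map's
gray-value scale, resolution, or sharpening level.

It is aimed at structural biologists interpreting single-particle
reconstructions or subtomogram averages: initial model building, assessment
of weak features (flexible loops, ligands, ions, water), and thresholding of
low-resolution averages where "what density is real?" cannot be judged by eye.

## Method

1. **Background null.** The noise distribution is estimated from cubic
   solvent windows outside the particle (four windows in the outer shell of
   the box by default; user-placed windows for off-centre particles and
   subtomogram averages): mean μ̂ and unbiased variance σ̂² of the pooled
   window voxels, under a Gaussian null — or an empirical upper-tail
   function when the background is visibly non-Gaussian.
2. **Voxel-wise one-sided tests.** Interpretable cryo-EM density is positive
   signal, so each voxel value *x* gets the upper-tail p-value
   p = 1 − Φ((x − μ̂)/σ̂).
3. **Multiple-testing correction under dependence.** Voxels are strongly
   correlated, so the p-values are adjusted with the Benjamini–Yekutieli
   step-up procedure, valid under arbitrary dependence. With m voxels,
   c(m) = Σₖ₌₁..m 1/k, and sorted p-values p₍₁₎ ≤ … ≤ p₍ₘ₎:

       q₍ᵢ₎ = min(1, min_{j ≥ i} m · c(m) · p₍ⱼ₎ / j)

4. **Confidence map.** Each voxel is assigned PPV = 1 − q. Thresholding at
   1 − α keeps exactly the voxels significant at FDR α; the recommended
   working threshold is 1% FDR (PPV 0.99). The confidence map is written as
   an ordinary MRC volume, so any viewer can contour it.
5. **Local SNR adjustment (optional).** When resolution varies strongly
   across the map, each voxel is low-pass filtered to its own local
   resolution (from a ResMap-style local-resolution map, discretised into a
   filter bank), and tested against the variance of background noise passed
   through the *same* filter. This recovers weak, smooth peripheral features
   at the same 1% FDR while leaving the error control intact. An externally
   computed per-voxel sigma volume can be supplied instead (`--sigma-map`).

Because the solvent windows tend to *over*-estimate the noise next to the
particle (greater water thickness than above it), the resulting confidence
is conservative: overestimating the variance can only lose signal, never
admit extra noise.

## Worked example

A synthetic 400×400 test image (two orthogonal cosine waves, period 5 px,
clipped and scaled to max 1, embedded in a zero frame) with Gaussian noise
of variance 0.01 added everywhere:

```sh
confmap simulate --mode grid2d --variance 0.01 --seed 3 --out demo
```

prints (abridged):

```
"snr": 2.8578,
"noise_mean_hat": 0.000668,  "noise_variance_hat": 0.009847,
"fdr_thresholds": {
  "0.01":  {"percent_voxels_detected": 5.84, "empirical_fdr": 0.00075, "recall": 0.449}
},
"sigma_3.0": {"percent_voxels_detected": 7.34, "empirical_fdr": 0.0171, "recall": 0.555}
```

Reading: the background estimate recovers the true noise (variance 0.0098 vs
0.01). At 1% FDR, 5.84% of pixels are detected with an *observed* false
discovery fraction of 0.075% — well inside the 1% guarantee (the BY
procedure is conservative). The conventional 3.0σ threshold detects slightly
more pixels but with a 1.7% false-positive contamination and no guarantee at
all. Files written: the clean and noisy phantoms, the confidence map, the 1%
FDR mask (all MRC) and the metrics JSON.

On a real map:

```sh
confmap run --input sharpened.mrc --output conf.mrc --fdr 0.01
confmap run --input sharpened.mrc --output conf_local.mrc --locres resmap.mrc
confmap diagnose-noise --input sharpened.mrc --out background.png
confmap metrics --map conf.mrc --mask conf_mask.mrc --pdb model.pdb
```

`run` writes the confidence map, the binary mask at the chosen FDR, and a
JSON report (noise mean/variance, window coordinates, m, c(m), percent
voxels detected at 0.01%/1%/10% FDR). Inspect `background.png` first if the
particle is off-centre and pass `--noise-box X Y Z --window-size N` to place
solvent windows manually.

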