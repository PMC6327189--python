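# Methods

## Model and assumptions

A cryo-EM map is modelled per voxel as signal + additive background noise.
The null hypothesis for a voxel is "background only"; the alternative is
one-sided (density of interest is positive signal — the overwhelming
majority of atomic density in sharpened maps is positive). The background
distribution is estimated from solvent regions of the box, under either

* a **Gaussian null** N(μ̂, σ̂²) with μ̂ the sample mean and σ̂² the unbiased
  (n−1) sample variance of the pooled window voxels, giving
  p(x) = 1 − Φ((x − μ̂)/σ̂); or
* an **empirical null**, where p(x) = (1 + #{bᵢ ≥ x}) / (n + 1) over the n
  pooled background values. The +1 continuity correction keeps every p-value
  strictly positive (a p of exactly 0 would break the rank semantics of the
  step-up adjustment) and bounds the smallest achievable p at 1/(n+1), so
  the empirical mode needs large windows to resolve small FDR levels.

Voxel-wise p-values are adjusted with the **Benjamini–Yekutieli** step-up
procedure, which controls the FDR under arbitrary dependence — the right
regime for reconstructions, whose voxels are correlated by the point-spread
function, interpolation and symmetry. m counts *every* voxel in the box,
including the background windows: the conservative choice, and the one that
makes "percent of voxels detected" directly comparable across maps. The
confidence map stores PPV = 1 − q; thresholding at 1 − α is identical to
selecting q ≤ α. In Gaussian mode p is monotone in the voxel value, and the
step-up adjustment preserves that order, so every detection set is a
superlevel set of the raw density: confidence maps can always be rendered as
isosurfaces.

Assumptions worth keeping in mind: the solvent windows must contain pure
noise (signal contamination inflates σ̂² and costs power; for subtomogram
averages place windows manually), and solvent-side noise tends to
*over*-estimate the noise under the particle (water displacement), so the
stated FDR is an upper bound, not an exact error rate.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window edge | 20 (clamped to ⌊min dim/4⌋) | voxels | centre of the 10–30 range where variance estimates are stable; clamping keeps 4 windows inside small boxes |
| window count/placement | 4, on the ±x/±y central axes, centre one edge in from the face | — | solvent shell of a centred particle; geometry is a package convention, parameterised and logged |
| FDR threshold | 0.01 | — | working threshold; 0.0001 and 0.1 always reported as stricter/looser diagnostics |
| p-value floor | smallest positive normal float64 | — | keeps ranks well defined; never influences any realistic threshold |
| resolution bin step | 0.5 | Å | filter-bank granularity vs cost; bins take the worst member resolution so no voxel is filtered sharper than measured |
| filter edge | 3 | Fourier pixels | raised-cosine roll-off wide enough to suppress ringing, narrow enough to be resolution-faithful |
| sigma scale | 1 | — | robustness experiments only; >1 is provably conservative (detection sets shrink monotonically) |

## Local SNR adjustment

The local-resolution field (Å, same grid, e.g. from ResMap) is discretised
into bins; the volume is Fourier low-pass filtered once per bin (transfer 1
below 1/resolution, raised-cosine to 0 over the edge width), and each voxel
takes its value from its bin's volume. The per-bin noise variance is
measured by applying the identical filter to the whole map and re-reading
the original background windows — filtering windows in isolation would
change the Fourier support and introduce edge artifacts. Each voxel is then
tested with its own σ (mean from the unfiltered background, where it is
unbiased). A cutoff at or beyond Nyquist is treated as an all-pass (a
spherical mask exactly at Nyquist would clip lattice corner frequencies), so
a uniform all-pass resolution field reproduces the global pipeline exactly —
a tested reduction. Local-resolution values below Nyquist are clamped up
with a warning; missing/zero values get the worst bin (conservative).

## Synthetic data

The **2D grid phantom** is the classic resolution-test pattern: two
orthogonal cosine waves of period 5 px are summed, values below 0 are set to
0, and the sum is halved so the maximum is exactly 1 ("clip then scale" —
the reading that makes the stated maximum come out exactly); the 200×200
patch sits centred in a 400×400 zero frame and i.i.d. Gaussian noise (mean
0, variance 0.01 / 0.1 / 1.33) is added over the whole frame, so the frame
border is pure noise and solvent-side estimation is valid. SNR is defined as
the full-frame variance of the noiseless image divided by the noise
variance, giving 2.86 / 0.286 / 0.0215 for the three variances. Note the
third condition lies *below* the SNR range the 2D study is designed around
(≈3.9 down to ≈0.3): there the step-up procedure detects essentially nothing
(measured: 0 detections per frame over 20 seeds), which is the correct
conservative behaviour — validation asserts super-chance detection-truth
overlap only within the designed SNR range, and asserts
zero-false-positive conservativeness at variance 1.33.

The **3D phantoms** embed soft-edged spherical blobs (raised-cosine radial
profile) in a pure-noise box, with a hard error if any signal reaches the
outer shell reserved for the default windows. The planted-signal condition
is a central sphere (r = 5, edge 2.5 voxels) of amplitude 8 noise-sd —
a strong, well-sharpened feature. The **two-region phantom** (96³) has a
fine-resolution core (3 Å, amplitude 8 sd) and six weak peripheral blobs
(3.5 sd, on the ±x/±y/±z axes at 12 voxels offset) in a 6 Å coarse region.
The peripheral blobs are ~11 voxels across, i.e. genuinely resolvable at the
coarse resolution: a blob much smaller than the local resolution would be
destroyed by its own filter, and its filtration blur would smear true signal
beyond the truth support, contaminating the empirical-FDR bookkeeping with
what is really a representation artifact rather than a statistical error.

What these phantoms do **not** emulate: structured (coloured) noise from
reconstruction algorithms, radially varying solvent noise, B-factor
amplitude decay, particle-boundary ambiguity, or model/atom-level
correctness. Passing tests therefore demonstrate the statistical properties
of the procedure (calibration, conservativeness, ordering vs σ thresholds,
local power gain), not end-to-end fidelity on deposited maps.

## Numerical choices

* Ties in p are broken by stable sort; the step-up minimum is a reversed
  running minimum; q is clipped to [0, 1].
* q-values below machine epsilon give PPV values that round to exactly 1.0
  in float64; PPV is stored as the elementwise complement and allowed to
  touch 1.0, while q itself is always > 0.
* Maps are written as MRC2014 mode 2 (float32); axis permutations
  (MAPC/MAPR/MAPS) are normalised on load to x-fast order; the origin is
  read from the ORIGIN header words, falling back to NXSTART offsets.
* Voxel indices are 0-based; a voxel's physical centre is
  origin + (index + 0.5)·voxel size. Atoms are assigned to their containing
  voxel under this convention; atoms outside the box are excluded from the
  inclusion fraction's denominator.
* Degenerate inputs fail loudly: non-finite voxels, constant background,
  zero/negative local sigma, overlapping windows, sub-Nyquist filter
  requests.

## Validation problem sizes

The statistical test-bed sizes — 20 seeds per grid-noise condition, 50
replicates each for pure-noise and planted-signal 64³ volumes, 3 seeds of
the 96³ two-region phantom — were chosen so the Monte-Carlo error on each
asserted mean is comfortably below the asserted margin while the whole
validation remains a desk-scale computation (tens of seconds).

## Known limitations

* Window placement is geometric, not content-aware; badly placed windows on
  off-centre particles silently inflate the variance (power loss). The
  `diagnose-noise` histogram is the intended guard.
* The empirical null cannot resolve p below 1/(n+1); with the default
  windows that bounds per-voxel significance before correction at ~3×10⁻⁵,
  which is often too coarse for small FDR levels on large boxes — use it for
  distribution-shape diagnosis, not for maximum sensitivity.
* The local filter bank assumes the local-resolution map shares the density
  map's grid; resampling is out of scope.
* Model-based local amplitude scaling is not implemented; an externally
  computed sigma volume can be injected via `--sigma-map`.
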