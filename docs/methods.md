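# Methods

## Measurement models

**Skin cleanability.** A delineated skin area soiled with the
sebum/carbon-black mixture is photographed before (T0) and after (T1)
washing. Let `f(I)` be the percent of area pixels with grey value strictly
below a threshold. The index is

```
cleanability% = (f(T0) − f(T1)) / f(T0) × 100 .
```

It is undefined at `f(T0) = 0` (an error) and may be negative when washing
deposits pigment; negative values are reported, with an optional clamp to
[0, 100] for display. The threshold instrument's criterion is not public,
so it is configurable: the default computes Otsu's threshold on the T0
image and reuses the same absolute grey level on T1, which keeps the
dark-pixel criterion identical within a pair (washing brightens the scene
and would otherwise shift an adaptive threshold). RGB input is reduced to
grey by ITU-R BT.601 luma.

**Hair-swatch cleanability.** With CIELAB lightness readings of the washed,
tainted and untreated-control swatch,

```
cleanability% = (L*_wash − L*_seb) / (L*_control − L*_seb) × 100 ,
```

defined only for `L*_control > L*_seb`. The index is invariant to adding a
constant to all three readings and to scaling both lightness differences.
The control is a single untreated swatch per measurement batch, measured
repeatedly; its reading noise is ~1 L\* unit (sd), and the batch mean of
the control readings enters the index. Replicates (6 per formula by
protocol) are aggregated as mean ± sample sd (n−1); replicates outside
[0, 100] — possible under noise — are flagged `out_of_range`, never
clamped. Plots clamp for display only. When readings come as images instead
of L\* values, sRGB is converted to CIELAB under D65 (scikit-image) and the
mean L\* of a centered 7.2 cm × 0.6 cm region of interest along the swatch
axis is used.

**Particle coverage (anti-deposit efficacy).** On a SEM-like micrograph the
fiber is a bright textured region on a darker background, carrying dark
quasi-circular CB particles. The pipeline:

1. *Fiber segmentation*: Otsu threshold on the grey image, binary closing
   (disk, 8 px) and hole filling, then the largest connected component.
   Fails ("no fiber found") if that component covers < 5% of the frame.
2. *Background elimination*: grey-level morphological closing with a square
   window of 5 mean particle diameters estimates the textured background
   (closing removes dark objects smaller than the window); the estimate is
   subtracted and the fiber's median level restored, so an already-flat
   fiber is left unchanged and particles keep their dark contrast. The
   window must be at least 3 particle diameters for single particles to be
   excluded from the estimate; 5 is the default so that clusters of a few
   overlapping particles are still removed. Windows that do not fit the
   image raise an error.
3. *Particle segmentation*: Otsu threshold on the flattened fiber-interior
   histogram (a fixed threshold is available for regression testing). If
   the Otsu split sits less than 10 grey levels below the fiber's neutral
   level the histogram is treated as unimodal — no particles — because real
   particles are rendered ≥ 20 grey levels below the flattened background.
   Components smaller than the equivalent-area disc of 0.5 µm are removed
   as sub-resolution speckle; edge-touching particles are kept because the
   statistic is areal, not a count (particle counts are emitted as QC only).
4. *Coverage*: `100 × |particle ∩ fiber| / |fiber|` — the denominator is
   the visible fiber area, not the frame.

Products are summarised over their fibers (18 per product by protocol;
other counts warn) as mean ± sample sd; per-image failures are recorded and
tolerated up to half the images. Categories (shampoo, conditioner, mask,
leave-on) are summarised by median/min/max of product means and ranked
ascending — lower coverage is better.

**Site calibration and ranking.** The forearm→scalp transfer is an OLS fit
`scalp ~ forearm` with R² the squared Pearson correlation (the standard
reading of a scatter-with-fit figure); it accepts formula-level means or
subject-level points. Formula ranking is ascending by mean cleanability
with a total tie-break (sd ascending, then formula id), so the order is
independent of input permutation.

## Synthetic data: what it emulates, and what it does not

All validation is parameter recovery against seeded generators
(`numpy.random.default_rng`; one integer seed per call; identical seed ⇒
bit-identical output).

- **SEM fields.** A vertical fiber band (40% of the field width) at grey
  level 160 with multiplicative cuticle-like texture (Gaussian random field,
  20 µm correlation length — cuticle cells are tens of µm — relative
  amplitude `noise_level`, default 0.08), background at 70 (≥ 30 grey
  levels separation so fiber masking is well-posed), pixel read noise sd 3.
  Particles are dark (grey ≈ 35) ellipses, axis ratio uniform in
  [0.7, 1.0], diameters from N(2.07, 0.3²) µm truncated at 0.5 µm (the
  dispersion is given without a named distribution; a truncated normal is
  the least-structured choice), placed uniformly on the fiber with overlap
  allowed; coverage is defined on the union mask, exactly as the pixel
  statistic measures it. Placement stops when the achieved coverage is
  within 0.25 pp of the target; candidates that would overshoot are
  rejected, and a target that cannot be reached raises an error naming the
  achieved maximum. The stored truth is recomputed from the masks, so
  oracle checks are exact. Default pixel scale 0.2 µm/px (mean particle
  ≈ 10 px; a 4 px minimum is enforced).
- **Skin pairs.** Dark pigment pixels (grey ≈ 45) scattered over light skin
  (grey ≈ 200) at the requested baseline fraction; washing keeps an exact
  random subset. The truth records pixel-exact fractions, so requested and
  true cleanability differ only by one-pixel rounding.
- **Swatch readings.** Noiseless wash lightness
  `L_seb + c/100 (L_ctrl − L_seb)` (the index inverted), each reading
  perturbed by N(0, 1) by default, matching the instrument's control sd of
  about 1. a\*/b\* carry plausible values but no signal.
- **Study tables.** Forearm values uniform over 5–100% (the observed
  formula range), scalp = slope·forearm + intercept + noise. Because the
  fitted R² of a 4-point OLS is biased upward relative to the population
  R², the noise sd that yields a desired *expected fitted* R² is found by
  bisection on a common-random-numbers Monte-Carlo estimate
  (`calibrate_study_noise`), not from the population formula.

Not emulated: electron-optics physics (charging, depth of field), sebum
film rendering, 3-D fiber curvature and cuticle edges, illumination
gradients in dermatoscope optics, panel-to-panel biological variability.
Passing recovery tests therefore demonstrates correctness of the
quantification given images whose contrast structure matches the protocol's
assumptions (dark particles on a brighter, smoothly textured fiber); they
do not certify performance on arbitrary real micrographs.

## Numerical choices and degenerate inputs

- Thresholds returned with every dark-pixel measurement; "dark" is strictly
  below the threshold. Otsu on a uniform image is undefined → fixed fallback
  128 with a warning (skin), or an empty particle mask (SEM).
- Sample statistics use the n−1 denominator; singleton groups report NaN sd
  and are flagged rather than dropped.
- Coverage tie-break: none needed — the statistic is a deterministic pixel
  count. Ranking ties are broken by sd, then id.
- Problem sizes in tests and the acceptance script: SEM fields 512×512 at
  0.2 µm/px (recovery sweeps at 256×256, 0.25 µm/px), 20 seeds per coverage
  level in the test sweep and 10 in the acceptance script; 100 seeds per
  cleanability truth; 1000 simulated 4-formula studies for the R² check.
  These sizes give Monte-Carlo error well below the acceptance margins.

## Known limitations

- The grey-closing background estimate biases the flattened image slightly
  dark inside particle clusters wider than the smoothing window; at ≤ 16%
  coverage this contributes < 0.2 pp absolute error.
- The Otsu-based particle threshold assumes ≥ ~10 grey levels of particle
  contrast after flattening; very low-contrast deposits would need the
  fixed-threshold mode.
- The 2.07 µm CB size (soiling mixture) and the 2.5 µm figure quoted for
  glove-box projection are both plausible inputs for the SEM arm; the
  particle diameter is therefore an explicit `SebollutionSpec` parameter
  with 2.07 as the default rather than a hard-coded constant.
- `cleanability_from_readings` treats the control as batch-wide; per-formula
  controls can be emulated by splitting the table before the call.
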