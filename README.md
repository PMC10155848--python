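# sebquant

Quantification pipelines for hair- and skin-care efficacy testing against a
model pollutant soil. Aerial particulate matter adheres to hair and scalp,
strongly promoted by sebum; efficacy studies therefore soil substrates with
"sebollution" — artificial sebum blended 9/1 (w/w) with carbon-black and
iron-oxide pigments (CB particle diameter 2.07 ± 0.3 µm) — and measure how
well products remove it or prevent particle deposition. `sebquant`
implements the three quantification protocols behind such studies, for
formulation scientists and image-analysis engineers who need them as
reproducible, testable code:

1. **Skin cleanability** (in vivo, dermatoscope images). The soiled area is
   photographed before (T0) and after (T1) washing; dark pixels are counted
   below a threshold (Otsu on T0, reused on T1) and

   `cleanability% = (T0_dark − T1_dark) / T0_dark × 100`.

2. **Hair-swatch cleanability** (in vitro, colorimeter readings). With
   CIELAB lightness L\* of the untreated control, tainted, and washed
   swatch,

   `cleanability% = (L*_wash − L*_sebollution) / (L*_control − L*_sebollution) × 100`.

3. **Anti-deposit efficacy** (SEM micrographs). Dark CB particles on the
   grey fiber are segmented after eliminating the fiber's textured
   background, and efficacy is the **coverage %** — the fraction of visible
   fiber surface occupied by particles (lower = better), summarised per
   fiber, per product (18 fibers by protocol) and per product category.

A fourth module calibrates the forearm as a proxy measurement site for the
scalp by ordinary least squares (scalp ~ forearm, reporting slope,
intercept and R²), and ranks formulae by cleanability.

Because no real study images or readings are publicly available, the
package ships a first-class synthetic-data generator
(`sebquant.synthetic_data`) that emits SEM-like fiber fields, skin image
pairs, swatch readings and paired-site tables **with exact ground truth**,
so every stage is validated by parameter recovery.

## Worked example

```python
import sebquant as sq

# render a SEM-like field at ~8% true particle coverage
image, truth = sq.generate_sem_field(target_coverage=8.0, seed=1)
print(f"true coverage: {truth.true_coverage:.3f}%")

cfg = sq.CoverageConfig(pixel_scale=0.2)   # µm per pixel
coverage, extras = sq.estimate_coverage(image, cfg)
print(f"estimated coverage: {coverage:.3f}% "
      f"({extras['n_particles']} particles)")

# hair cleanability from L* readings: washed 65, tainted 35, control 85
print(f"cleanability: {sq.cleanability_hair(65.0, 35.0, 85.0):.1f}%")
```

prints

```
true coverage: 7.816%
estimated coverage: 7.795% (97 particles)
cleanability: 60.0%
```

The estimated coverage differs from the generator's truth by 0.02
percentage points; across the 0–16% coverage range the mean absolute
recovery error is below 0.1 pp at the default texture noise. The
cleanability value is the exact closed-form index: the wash recovered 30 of
the 50 lost L\* units.

The same operations are available from the shell:

```bash
sebq config --dump                 # all defaults as YAML
sebq simulate sem --seed 1 --out-dir sim/
sebq coverage --manifest sim/manifest.csv --out-dir results/
sebq run --seed 17 --out-dir results/   # full simulate→quantify→analyze run
```

`sebq run` writes per-area/per-formula cleanability tables, per-fiber /
per-product / per-category coverage tables, the site-calibration fit,
ranking and reproducibility reports, figures, and a provenance record;
rerunning with the same seed reproduces every CSV byte for byte.

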