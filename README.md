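# artstat

Statistical image analysis for empirical aesthetics: compute low-level
image statistics on paintings, genre by genre, and relate them to
aesthetic ratings.

A long line of work has asked whether some universal low-level image
property — fractal dimension, the slope of the Fourier amplitude
spectrum, entropy — predicts how beautiful people find images.
Evidence for a single universal statistic is weak; a more plausible
picture is that *different* statistics matter for paintings with
different subject matter.  `artstat` implements the full analysis
needed to test that idea on any image collection with ratings:

1. **Preprocess** — crop each image to its largest central square,
   resize to 1024×1024 with bicubic interpolation, convert to CIELAB,
   and split into the L (lightness), a (red–green) and b (blue–yellow)
   planes.
2. **Statistics** — on each plane, estimate
   - the **spectral slope** SL: the slope of the rotationally averaged
     Fourier amplitude spectrum on log–log axes (natural images sit
     near −1.2),
   - the **fractal dimension** FD: a 3-D box-counting estimate of how
     thoroughly the intensity surface fills the (x, y, intensity)
     volume, from 0 (uniform field) to 3 (space-filling),
   - the **entropy** EN: Shannon entropy of the 256-bin intensity
     histogram, from 0 bits (constant) to 8 bits (uniformly random
     8-bit image),

   giving the nine-element vector SL(L) … EN(b) per image.
3. **Correlation screen** — Pearson correlations between ratings and
   each statistic, per genre and pooled, reported as coefficients of
   determination Cd = 100·r² and screened with Benjamini–Hochberg FDR
   at q = 0.05.
4. **PLSR + VIP** — partial least squares regression of ratings on the
   z-scored nine-statistic matrix (robust to the strong collinearity
   among the statistics).  The component count is the smallest
   reaching 85% of the asymptotic in-sample fit; variable importance
   in projection (VIP) scores — whose squares average exactly 1 —
   flag the statistics driving each genre's model at the VIP > 1.25
   criterion.
5. **Genre comparison** — one-factor ANOVAs of each statistic on
   genre, Tukey-HSD comparisons over all 28 genre pairs, and boxplot
   summaries.

A first-class synthetic-data module generates images with prescribed
spectral exponents, fractal (Hurst) roughness and histogram entropy,
plus rating datasets with known generative weights, so the entire
pipeline is testable without access to any artwork database.

## Worked example

Simulate an 8-genre image set (power-law colour textures whose
lightness spectral exponent varies by genre and drives the ratings),
then run the full pipeline:

```bash
artstat simulate --out demo --n-images 80 --size 256 --seed 42
artstat run --config demo.yaml     # or, in Python:
```

```python
from artstat.synthetic import simulate_genre_images
from artstat.pipeline import PipelineConfig, run_pipeline

img_dir, meta = simulate_genre_images("demo", n_images=80, size=256, seed=42)
paths = run_pipeline(PipelineConfig(image_dir=str(img_dir), metadata=str(meta),
                                    out_dir="demo/out", side=256, seed=42))
```

`stats.csv` holds the nine statistics per image:

```
 image_id     genre  rating   SL_L   SL_a   SL_b  FD_L
img_00000  abstract  28.545 -0.664 -0.992 -0.992 2.785
img_00001 landscape  78.372 -1.483 -0.992 -0.992 2.413
img_00002    people  69.867 -1.222 -0.991 -0.992 2.558
```

The abstract image was generated with a shallow spectral exponent
(≈ −0.7) and the landscape with a steep one (≈ −1.3); the estimated
SL(L) values recover that, and the rougher abstract texture also has
the higher FD(L).  The pooled correlation rows
(`correlations.csv`):

```
genre statistic  n       r      Cd  significant
  all      SL_L 80 -0.7362 54.1994         True
  all      FD_L 80 -0.7189 51.6887         True
  all      EN_L 80  0.4942 24.4208         True
```

Ratings were generated to rise with steeper lightness spectra, so
SL(L) carries the largest share of rating variance (Cd ≈ 54%); FD(L)
inherits much of it through collinearity.  The PLSR summary
(`plsr.csv`) gives, per genre, the selected component count, the model
fit and the nine VIP scores:

```
    genre  n  n_comp  cd_fit  SL_L  EN_L
      all 80       1  53.849 1.870 1.255
 abstract 10       7  97.801 1.416 0.859
landscape 10       3  85.022 1.219 0.403
```

In the pooled model SL(L) is the only statistic clearing the
VIP > 1.25 criterion, matching the generative ground truth.  The
ANOVA table confirms the built-in genre differences
(`anova.csv`: SL(L): F(7, 72) = 52.3, p < 1e-15).

## Command-line interface

`artstat` exposes each stage as a subcommand:

```
artstat preprocess --images DIR --out DIR        # .npz CIELAB plane stacks
artstat compute    --images DIR --meta meta.csv --out stats.csv
artstat correlate  --stats stats.csv --out correlations.csv
artstat plsr       --stats stats.csv --genre nude --out model.json
artstat genres     --stats stats.csv --out anova.csv --plots plots/
artstat simulate   --out DIR --n-images 200 --size 256 --seed 0
artstat run        --config pipeline.yaml
```

The metadata CSV has columns `image_id, genre, rating[, rating_scale]`;
ratings tagged `mart7` (7-point scale) are affinely rescaled onto the
100-point scale via x ↦ (x−1)·100/6 so differently scaled rating sets
can be pooled.
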