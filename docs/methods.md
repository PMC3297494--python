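# Methods

## Measurement model

For a field imaged in two planes — green/FITC carrying the target protein
(NAIP), red/Texas Red carrying the housekeeping reference (GAPDH) — and a
label mask delineating cells, the per-cell score is the quotient of the
arithmetic means of the raw pixel intensities over exactly the labelled
pixels:

    ratio_i = mean(green[mask == i]) / mean(red[mask == i])

No background subtraction is applied by default (an optional
rolling-minimum subtraction is available behind a flag). Two properties
drive that choice and are asserted by the test suite:

- **Gain invariance.** A common multiplicative factor on both planes
  (illumination, exposure, detector gain) cancels exactly; scaling only the
  green plane by c scales every ratio by exactly c.
- **Offset sensitivity.** A common *additive* offset b > 0 pulls every
  ratio toward 1. Ratios are therefore only comparable across images with
  comparable background; the synthetic fixtures default to zero background
  for this reason, and real data with appreciable background should use the
  subtraction flag consistently.

Cells are excluded, with a logged warning, when the housekeeping mean is
zero (no reference signal — the score is undefined) or the labelled area is
below `min_cell_area`; cells touching the image border are excluded because
truncation of the footprint biases the means.

A sample is summarized by its *cell collection*: a uniform random subset of
`k_cells = 30` measured cells drawn without replacement across all the
sample's fields (all cells, with a warning, if fewer are available). The
summary is the mean ratio M.R and the sample standard deviation (n − 1
denominator) of the collection's ratios. The ± values attached to M.R
throughout are SDs, not standard errors; consumers holding SEMs must
convert first (`--plusminus=sem` in the CLI). Pooling the collection across
a sample's fields (rather than per field) is a deliberate convention, as is
uniform sampling: cell-type preferences used by human raters are not
computable from a mask and are out of scope.

## Segmentation

The primary path consumes supplied label masks (the digitized equivalent of
manual boundary selection). The automated stand-in (`segment_cells`)
thresholds the *red* plane — the housekeeping stain marks every cell —
with Otsu's method, labels 8-connected components, removes components below
`min_cell_area` (default 20 px), and relabels in raster order. A blank
field yields an empty mask, not an error. This is intentionally minimal; it
is adequate for the generator's well-separated cells and is not a general
segmentation solution (no watershed splitting of touching cells, no
intensity-based refinement).

## Synthetic micrograph generator

Each sample is described by a `SyntheticSampleSpec`. Per field, the
generator:

1. draws per-cell expression ratios from N(`true_mean_ratio`,
   `between_cell_sd`) truncated at 0, and per-cell housekeeping levels from
   N(`red_mean_level`, `red_cell_cv · red_mean_level`) truncated at 0;
2. quantizes each cell to the integer pixel grid: red level r = round(draw),
   green level g = round(ratio · r), and stores `true_ratio = g/r` as the
   ground truth — so on a noise-free, zero-background field the measured
   ratio equals the stored truth to floating-point rounding, despite
   integer-valued TIFF output. The quantization perturbs the pre-quantization
   draw by at most 0.5/r (≈ 5·10⁻⁴ at the default red level of 1000);
3. places cells as non-overlapping ellipses (uniform radii in
   `cell_radius_range`) by rejection sampling, fully inside the image, with
   a bounded attempt budget (500/cell) — a too-crowded field raises an
   error naming the sample;
4. renders red = r + background and green = g + background inside each
   ellipse, adds i.i.d. Gaussian noise of SD `pixel_noise_sd`
   to every pixel of both planes (or replaces values by Poisson draws in
   `noise_model="poisson"`), clips to the bit-depth range (saturation is
   logged with the overflow fraction; negative excursions floor silently at
   the dark level), rounds, and writes 16-bit (default) or 8-bit TIFFs plus
   a label mask.

All randomness derives from `SeedSequence([seed, sha256(sample_id)[:4],
image_index, stage])`, with separate stages for truth draws, pixel noise
and collection sampling: samples and fields are independent,
order-insensitive, and byte-identically regenerable.

Group-level studies (`build_group_specs`) draw each sample's
`true_mean_ratio` from N(group mean, `between_sample_sd`), modelling
biological variation between tissue blocks of one diagnostic group; the
group mean is the generator truth recovered by the pipeline.

### What the generator does and does not emulate

It reproduces the features the ratio estimator depends on: two co-registered
planes, approximately constant housekeeping level with cell-to-cell CV,
green level proportional to a latent per-cell ratio, pixel noise, integer
quantization, and the study's sampling design (fields per sample, cells per
collection, group sizes). It deliberately omits point-spread-function blur,
photobleaching, spectral bleed-through, autofluorescence gradients,
touching/overlapping cells and cell-type heterogeneity. Passing tests
therefore validate the *computational* pipeline — measurement, sampling,
summarization, inference — not the immunostaining itself; systematic wet-lab
effects (uneven background, bleed-through) would bias real ratios in ways
no amount of synthetic testing can exclude.

## Default study conditions

The default simulated study mirrors the published design: groups HL
(39 samples, M.R 0.5834 ± 0.021), NHL (23, 0.6040 ± 0.026), normal (30,
0.5882 ± 0.047), RLH (9, 0.6365 ± 0.017), control = normal+RLH pooled (39,
0.5987 ± 0.045), with 30-cell collections. Parameters the source study does
not determine were fixed once at realistic values and are stated in
`ratioquant.presets`:

| parameter | default | rationale |
|---|---|---|
| `between_cell_sd` | 0.05 (ratio units) | cell-to-cell spread; contributes 0.05/√30 ≈ 0.009 to the sample-level M.R SD, small next to the printed between-sample SDs |
| `red_mean_level` | 1000 (16-bit ADU) | mid-range housekeeping signal, far from saturation |
| `red_cell_cv` | 0.10 | moderate staining variability; cancels in the ratio |
| `pixel_noise_sd` | 30 ADU | SNR ≈ 33 in-cell, "moderate noise" |
| `background_level` | 0 | see offset sensitivity above |
| fields × cells | 3 × 10 (128×128 px, radii 4–8) | exactly 30 measurable cells per sample at small field size |

The replicated-study simulations (power pattern, null calibration) and the
study-scale run use reduced field sizes (96–128 px, 2–10 cells/field) so
that hundreds of full render→measure→summarize replicates complete quickly
on one CPU; the statistical structure (group sizes, collection size, noise
level, between-sample SDs) is kept at the published values. The
study-scale run itself uses 101 samples × 20 fields with 30-cell
collections (3,030 analyzed cells).

## Statistical layer

- Two-sample t-tests are two-sided; *pooled* (common variance, df =
  n₁+n₂−2) is the default, Welch–Satterthwaite optional. Degenerate inputs
  follow explicit conventions: both groups constant and equal → t = 0,
  p = 1; constant and unequal → p = 0 with an infinite statistic and a
  warning.
- `t_test_from_summaries` computes the identical test from (n, mean, SD)
  triples and is exactly equivalent to the raw-data test on any data with
  those summaries (verified by construction in the tests).
- One-way ANOVA reports F, (df_between, df_within), p; for two groups
  F = t² (pooled) to 1e-10. Zero total variance is rejected as degenerate.
- Fisher's exact test (2×2 only) sums hypergeometric probabilities ≤ the
  observed table's at fixed margins; the suite verifies it against
  exhaustive enumeration for every 2×2 table with N ≤ 40. χ² is the plain
  Pearson statistic without continuity correction, with a warning when any
  expected count is below 5.
- No multiple-testing correction is applied anywhere; reports state the
  number of tests performed and show raw p values.
- `type_one_error_sim` calibrates the pooled t under the null by drawing
  per-cell ratios from the generator's truncated-normal distribution
  (30-cell sample means, both groups from one spec) — the inference layer
  is what this simulation validates, so fields are not rasterized;
  image-level behaviour is covered by the replicate machinery in
  `ratioquant.pipeline`, which renders every field.

## Numerical and interface conventions

- Coordinates are 0-based (row, col); masks use 0 = background, gaps in
  label ids are allowed.
- Intensities are never rescaled on read; measurement CSVs are written with
  17 significant digits and parsed back with a round-trip float parser, so
  ratios survive save/load bit-for-bit.
- Reports display M.R ± SD at 4 decimals; the CSVs beside them keep full
  precision. The provenance block (config hash — excluding the output
  directory — seed, version) is sufficient to regenerate every number, and
  reruns are byte-identical.
- Seeds are consumed as 32-bit integers; any Python int is accepted and
  reduced mod 2³².

## Known limitations

- Otsu-based segmentation assumes well-separated cells on a darker
  background; it will merge touching cells.
- The truncated-normal ratio model is an assumption — the source design only
  constrains sample-level means and SDs; heavier-tailed per-cell
  distributions would widen collection SDs but leave M.R unbiased.
- With nonzero `background_level` the stored per-cell truth refers to the
  background-free signal; measured ratios are then biased toward 1 by
  construction (the documented offset effect), so recovery checks use zero
  background.
- The χ²/Fisher layer treats tables as fixed-margin counts; no stratified
  or paired designs.
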