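# ratioquant

Semi-quantitative analysis of dual-channel immunofluorescence micrographs:
per-cell target/housekeeping intensity ratios, fixed-size cell collections,
sample mean ratios, and group-level hypothesis tests — plus a synthetic
micrograph generator with known per-cell ground truth so the whole pipeline
is testable without any real slides.

## The problem

Protein expression in FFPE tissue sections is often scored from two-color
immunofluorescence: the target protein (here NAIP, stained with FITC, the
*green plane*) is imaged alongside a housekeeping protein with assumed
constant expression (GAPDH, stained with Texas Red, the *red plane*). For
each manually or automatically delineated cell the expression score is

```
ratio = mean green pixel intensity over the cell
        ----------------------------------------
        mean red pixel intensity over the same cell
```

Because both planes share illumination and exposure, the ratio is invariant
to any common multiplicative gain; dividing by the housekeeping signal is
what makes the score comparable across fields, slides and sessions. A
sample (one tissue block, 20–30 fields) is summarized by the mean ratio
**M.R** and standard deviation of a fixed-size random *cell collection*
(default 30 cells pooled across the sample's fields). Diagnostic groups
(e.g. Hodgkin lymphoma vs. non-neoplastic controls, or reactive lymphoid
hyperplasia vs. normal nodes) are then compared with two-sample t-tests
(pooled by default) and one-way ANOVA on the sample M.R values, and
clinical-feature count tables with χ²/Fisher exact tests.

Since the original slides are never available, the package ships a forward
model: elliptical, non-overlapping cells with truncated-normal per-cell
ratios and housekeeping levels, additive Gaussian (optionally Poisson)
pixel noise, rendered to 8/16-bit grayscale TIFF pairs plus label masks,
with every draw reproducible from `(seed, sample_id, image_index)`.

## Worked example

A two-group synthetic study (9 reactive-hyperplasia-like samples with true
group M.R 0.6365 ± 0.017 against 30 normal-like samples with 0.5882 ±
0.047, 30-cell collections from 3 fields × 10 cells per sample):

```sh
ratioquant run --config study.yaml
```

prints the group table and writes `cells.csv`, `samples.csv` and the report:

```
group            n_samples  M.R ± SD
RLH                      9  0.6356 ± 0.0230
normal                  30  0.5738 ± 0.0538

group_a         group_b         method     statistic          df         p
RLH             normal          t_pooled      3.3291        37.0  0.001981
```

The recovered group means (0.6356, 0.5738) sit within sampling error of the
generator truths, and the pooled t on the 39 sample M.R values rejects
equality (p ≈ 0.002). The same test can be run directly from printed
summary statistics, treating the ± values as SDs:

```sh
$ ratioquant stats --summaries printed.csv
RLH vs normal [t_pooled]: t = 3.0006, df = 37, p = 0.004803
```

i.e. the published RLH vs normal difference is significant at the 1% level
from its printed summaries alone. Contingency tables are tested with
`ratioquant stats --table counts.csv` (χ², plus Fisher exact for 2×2).

See `docs/methods.md` for the model, its assumptions and parameter
conventions.

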