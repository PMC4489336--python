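# wgsig

Significance thresholds for whole-genome sequencing association scans that
combine single-marker F-tests of common variants with overlapping
sliding-window tests (burden, SKAT, SKAT-O) of rare variants.

Correlated window statistics make a plain Bonferroni correction too strict.
`wgsig` quantifies that dependence two ways and converts it into a
family-wise-error-calibrated per-test significance level:

* **Analytic route** — closed-form null correlations between window test
  statistics (trace formula for SKAT quadratic forms, squared projected-score
  correlation for burden), eigendecomposition of the banded correlation
  matrix, and effective-number-of-tests estimators (Li–Ji and Li et al.).
* **Empirical route** — simulate null phenotypes, run every test for every
  replicate, partition the chromosome into contiguous sections of varying
  size, take the 5th percentile of per-section minimum P-values, regress the
  empirical thresholds against the Bonferroni scale, and extrapolate the
  fitted line to the genome-wide test count.

A built-in synthetic-cohort generator (founder haplotypes with a rare-skewed
allele-frequency spectrum and distance-decaying LD, mosaic copying, null
Gaussian phenotypes) makes every stage testable without access to any real
cohort.

## Package layout

| module               | contents |
|----------------------|----------|
| `wgsig.genotypes`    | VCF loading, MAF partitioning, 50-variant / 25-step window tiling |
| `wgsig.synthetic`    | synthetic cohorts (founders, mosaic copying, phenotypes, VCF writer) |
| `wgsig.association`  | single-marker F, burden, SKAT, SKAT-O, quadratic-form P-values |
| `wgsig.store`        | `PValueStore` and the vectorized batch test runner |
| `wgsig.correlation`  | analytic inter-window null correlations, banded storage |
| `wgsig.effective`    | eigenvalue spectra, m_e estimators, threshold arithmetic |
| `wgsig.threshold`    | section/percentile/regress/extrapolate pipeline |
| `wgsig.workflow`     | run configs and the two end-to-end studies |
| `wgsig.cli`          | `wgsig` command-line interface |

## CLI

```bash
# write a synthetic cohort as VCF + phenotype TSV
wgsig simulate-cohort --n-individuals 500 --n-sites 50000 --seed 1 \
    --out-prefix scratch/cohort

# null P-values for every window (and single-marker) test
wgsig run-tests --synthetic --maf-threshold 0.01 --test burden \
    --replicates 200 --seed 1 --out scratch/pvalues.tsv

# analytic inter-window correlations and the implied m_e
wgsig null-correlations --synthetic --kind skat --band 200 \
    --seed 1 --out scratch/band.tsv
wgsig meff --corr scratch/band.tsv --method li_ji

# full empirical pipeline with genome-wide extrapolation
wgsig estimate-threshold --synthetic --test burden --maf-threshold 0.01 \
    --replicates 1000 --sections 1024 --seed 1 --out-dir scratch/run
wgsig report --out-dir scratch/run
```

Real data enter through `--vcf` (plain or bgzipped VCF with GT fields) plus a
phenotype TSV with columns `sample_id<TAB>phenotype`.

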