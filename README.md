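# labscan

Quality control of EHR laboratory values and lab-wide association scanning.

`labscan` turns raw long-format clinical lab observations (one row per
patient × lab × draw, values as recorded free text) into analysis-ready
per-patient summaries, and scans them for association with a standardized
predictor such as a polygenic score or a diagnosis flag.

The package has four parts:

- **`labscan.qualitylab`** — the cleaning cascade: unit canonicalization
  (synonym table, e.g. `mcg/L` = `μg/L`), catalog-level filters (labs must
  be numeric, multi-patient, unit-concordant ≥ 70%, with ≥ 100 patients and
  ≥ 1000 numeric observations by default), observation-level filters
  (strict numeric parse, modal-unit restriction, a single-pass 4-SD outlier
  fence), per-patient medians with age-at-median, optional pre-event
  truncation and patient exclusion, rank-based inverse normal
  transformation (Blom offset 3/8), and stratified summary statistics.
- **`labscan.labwas`** — per-lab ordinary least squares of the INT values on
  a standardized predictor, adjusting for sex, a restricted cubic spline of
  median record age (4 knots at Harrell quantiles), principal components and
  optional extra covariates; t-based p-values and 95% CIs; Bonferroni
  threshold `alpha / (n_labs_tested × n_scans)`; a triangle scan plot.
- **`labscan.synthdata`** — a generator for synthetic cohorts and raw
  observation tables with known per-lab standardized effects, unit dialects,
  contamination (non-numeric / infinite / gross-outlier entries), uneven
  observation counts and medication-style event shifts, plus an independent
  brute-force oracle that re-derives every QC decision from the truth ledger.
- **`labscan.cli` / config / validation** — a `labscan` command-line tool,
  YAML configuration with strict unknown-key rejection, table schema
  validation and JSON run manifests with input digests.

## CLI

```sh
# generate a synthetic cohort (see tests/test_cli.py for a config example)
labscan synth --config config.yaml --seed 1 --out-dir synth/

# clean raw observations into the per-patient median/INT table
labscan clean --obs synth/observations.tsv --config config.yaml \
    --out-dir clean/ [--unit-map units.tsv] [--event-ages events.tsv] \
    [--exclude patients.txt] [--demographics demo.tsv]

# association scan and plot
labscan scan --clean clean/clean_table.tsv --predictor synth/predictor.tsv \
    --covariates synth/covariates.tsv --out scan/ \
    [--allowlist labs.txt] [--adjust diagnosis] [--n-scans 4] [--min-n 100]
labscan plot --results scan/scan_results.tsv --out scan.png

# schema checks
labscan validate --table clean/clean_table.tsv --schema clean
```

Every command writes a `manifest.json` with its configuration echo, input
SHA-256 digests and record counts.

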