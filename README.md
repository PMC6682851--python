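# screentriage

Feasibility analysis of AI-based pre-selection of normal screening
mammography exams, as a tested, fully synthetic-data-driven pipeline:

* **`reading_data`** — data model and CSV I/O for exams, multi-reader
  malignancy scores and the (split-plot) study design.
* **`synthetic_cohort`** — seeded generator of exams with per-class AI-score
  category distributions and of correlated radiologist scores (Gaussian
  latent model, fully crossed within each study block).
* **`triage_engine`** — decile calibration of a continuous AI score into
  categories 1–10, threshold-sweep partitioning into excluded/pre-selected
  groups, exclusion statistics, and reassignment of radiologist scores of
  excluded exams to their scale minimum.
* **`mrmc_inference`** — per-reader trapezoidal ROC/AUC, area-preserving
  reader-averaged ROC curves (averaging perpendicular to the chance line),
  an unbiased U-statistic variance estimator of the reader-averaged AUC for
  arbitrary (including split-plot) designs, and Bonferroni-corrected
  non-inferiority comparison of triage scenarios (margin 0.05).
* **`pipeline_cli`** — one-command orchestration with a JSON run manifest.

## CLI

```bash
# synthetic 2654-exam split-plot cohort (9 blocks, 4 readers each)
screentriage simulate --preset fixture --seed 7 --out outdir

# exclusion/workload trade-off for thresholds 1..9
screentriage triage --exams outdir/exams.csv --readings outdir/readings.csv \
    --out outdir/tradeoff.csv

# MRMC non-inferiority comparison (original + 9 pre-selection scenarios)
screentriage evaluate --exams outdir/exams.csv --readings outdir/readings.csv \
    --margin 0.05 --out outdir/mrmc.csv

# full pipeline from a YAML config, plus a readable summary
screentriage run --config run.yaml --seed 7 --out outdir
screentriage report --manifest outdir/manifest.json
```

A minimal `run.yaml`:

```yaml
cohort:
  preset: fixture        # or n_normal/n_benign/n_cancer [+ reader_model]
thresholds: [1, 2, 3, 4, 5, 6, 7, 8, 9]
margin: 0.05
```

Outputs: `exams.csv`, `readings.csv`, `tradeoff.csv`, `mrmc.csv`,
`roc_curves.csv`, `manifest.json`.  In `tradeoff.csv` the `pct_*` columns are
percentages per truth class; the two `workload_reduction_*` columns are
fractions (of normal exams, i.e. of a screening workload, and of the whole
enriched sample respectively).  Identical config + seed gives byte-identical
outputs.

## Semantics

At threshold `t` (1–9) an exam is excluded from human reading iff its AI
category is `<= t`; its radiologists' scores are reassigned to the minimum of
their scale (the exam is auto-reported normal), while readings of
pre-selected exams are left untouched.  ROC positives are cancer exams;
benign and normal exams are negatives.  Non-inferiority of a scenario versus
the original reading is declared when the Bonferroni-corrected 95% CI lower
bound of the reader-averaged AUC difference exceeds −0.05.

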