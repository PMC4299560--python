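# ctild

Quantitative CT analysis of interstitial lung disease: threshold-based lung
segmentation, density-mask fibrosis-fraction scoring, Warrick-style visual
scoring, and the cohort statistics (Pearson correlation/regression,
inter-reader ICC, ROC criterion table with Youden-optimal cutoff) that tie
image-derived and reader-derived scores together.  Everything is exercised
on synthetic CT phantoms and synthetic patient cohorts with known ground
truth, so the full pipeline is testable without any clinical data.

## What it computes

* **Lung segmentation** — voxels inside an inclusive HU band (default
  [-1024, -200]), with exterior air, the tracheal air column, small
  components and optional per-slice polygonal exclusions removed
  (`ctild.segmentation`).
* **Fibrosis fraction** — `100 * (N_total - N_nonfibrotic) / N_total`,
  where N_total counts masked voxels in [-1024, -200] HU and
  N_nonfibrotic those in [-1024, -700] HU; plus mean lung attenuation,
  skewness and (un-excess) kurtosis of the masked histogram
  (`ctild.densitometry`).
* **Visual scoring** — severity points per abnormality (ground glass 1 …
  subpleural cysts 5), extent grades from involved-segment counts
  (1–3 → 1, 4–9 → 2, >9 → 3), totals 0–30, mild/severe split at >7
  (`ctild.warrick`).
* **Cohort statistics** — Pearson r with regression line, ICC(2,1)
  (absolute agreement; consistency form also available), pooled t /
  chi-square group comparisons, and ROC analysis with trapezoidal AUC,
  Hanley–McNeil SE, and a full criterion table (Clopper–Pearson CIs,
  likelihood ratios with log-method CIs, predictive values)
  (`ctild.stats`).
* **Synthetic data** — CT phantoms with exact lung masks and fibrotic
  fractions (`ctild.phantom`), and patient cohorts whose observed
  correlations, reader ICC and column moments are calibrated to requested
  targets via a Gaussian copula with moment-matched Beta marginals
  (`ctild.cohort`).

Volumes travel as DICOM series (a minimal explicit-VR-little-endian
reader/writer ships with the package) or NIfTI; masks as NIfTI; tables as
CSV; reports as JSON.

## CLI

```sh
ctild phantom --spec spec.yaml --seed 7 --out phantom_dir     # synthetic CT + truth
ctild cohort --seed 7 --out cohort.csv                        # synthetic cohort
ctild segment --in phantom_dir/series --out mask.nii.gz       # lung mask
ctild quantify --in phantom_dir/series --mask mask.nii.gz \
    --bands "-1024:-700:-200" --out result.json               # fibrosis fraction
ctild warrick --in findings.csv --out scores.csv              # visual scoring
ctild stats --cohort cohort.csv --dichotomize warrick_mean:7 \
    --score cam_extent_pct --out report/                      # ROC + criterion table
ctild run --config config.yaml                                # full pipeline + manifest
```

A pipeline config is a YAML mapping, e.g.

```yaml
output_dir: out
seed: 5
phantom: {target_fibrotic_fraction: 0.30, noise_sd: 20.0}
bands: [-1024, -700, -200]
```

## Layout

```
src/ctild/
  phantom.py       synthetic CT phantoms with ground truth
  cohort.py        synthetic cohorts with calibrated statistics
  segmentation.py  threshold lung segmentation + manual exclusions
  densitometry.py  fibrosis fraction, MLA/skewness/kurtosis
  warrick.py       visual scoring tables and CSV interface
  stats.py         correlation, ICC, group tests, ROC criterion table
  dicomio.py       minimal explicit-VR-LE DICOM slice reader/writer
  io.py            DICOM/NIfTI/CSV/JSON plumbing
  pipeline.py      orchestration, config, run manifest
  cli.py           click-based `ctild` command
```
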