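# karyotex

Nuclear chromatin texture analysis for single-nucleus cytology images:
geometric morphometry, gray-level co-occurrence (GLCM) texture features, a
pseudo-3D blanket (Minkowski–Bouligand) fractal dimension with a
goodness-of-fit R², and the cohort statistics needed to compare two patient
groups — Mann–Whitney, Spearman, exact (Clopper–Pearson) binomial confidence
intervals, and univariate / stratified Cox regression.

Because no public image set accompanies this kind of study, the package
ships a seeded synthetic generator that produces two-group cohorts of
nucleus images (oval or bilobed masks filled with fractional-Brownian
chromatin surfaces) with known ground truth, so the whole pipeline is
testable offline.

## Package layout

| module                | contents |
|-----------------------|----------|
| `karyotex.synthetic`  | seeded nucleus/cohort generator (masks, fBm surfaces, gray rendering, survival draws) |
| `karyotex.io`         | PNG/TIFF reading, RGB→8-bit luminance (Rec.601), mask binarization |
| `karyotex.morphometry`| nuclear area (μm²), form factor 4πA/P² (chain-code perimeter), gray mean/SD |
| `karyotex.glcm`       | 256-level symmetric co-occurrence matrix over the mask; entropy, contrast, local homogeneity, cluster prominence |
| `karyotex.fractal`    | blanket dilation series V(ε), A(ε); log–log fit → FD = 2 − slope, R² |
| `karyotex.stats`      | patient aggregation, Mann–Whitney, Spearman, Clopper–Pearson CI, Cox (Breslow ties, optional strata) |
| `karyotex.pipeline`   | feature CSV and report CSV orchestration |
| `karyotex.cli`        | `karyotex` command (see below) |

## CLI

```bash
# generate a synthetic cohort (PNG images + masks, manifest.csv, patients.csv)
karyotex simulate --seed 42 --out cohort/

# per-nucleus features (10 columns: area, form factor, gray mean/SD,
# entropy, contrast, local homogeneity, cluster prominence, FD, R²)
karyotex features --manifest cohort/manifest.csv --calibration 0.1 --out features.csv

# patient medians + group comparison, correlations, Cox (univariate and
# stratified) CSVs
karyotex stats --features features.csv --patients cohort/patients.csv \
    --group group --strata group --out reports/

# everything in one deterministic run
karyotex report --seed 42 --out run/
```

All randomness flows from the single seed; reruns with the same seed and
config are byte-identical. Feature options (GLCM log base, blanket ε range
and normalization, calibration in μm/pixel) are CLI flags; generator
parameters can be given as YAML (`--config`).

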