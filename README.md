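# pettex

Quantifying PET tumor-texture response to treatment, end to end and on
synthetic data: seeded 3D tumor phantoms, fuzzy Bayesian tumor delineation,
64-bin gray-level quantization, a 114-feature 3D texture engine (geometric,
fractal, first-order, GLCM, GLRLM/GLSZM/NGTDM), and a two-group statistical
pipeline with correlation-based feature reduction, a Bonferroni gate and
fold-change reporting.

## Layout

| module | what it does |
| --- | --- |
| `pettex.phantoms` | seeded phantom generator: lobulated tumor masks, capacity-balanced Voronoi zone partitions with controllable size dispersion, uptake-class coloring, Gaussian PSF, multiplicative noise; two-arm cohorts |
| `pettex.segmentation` | deterministic 3-class fuzzy Bayesian classification (background / partial-volume / tumor) with a 26-neighborhood spatial prior; VOI extraction |
| `pettex.matrices` | 64-bin quantizer and the four texture matrices (GLCM, GLRLM, GLSZM, NGTDM) on the 3D lattice, 13 directions / 26-connectivity |
| `pettex.features` | the 114-feature catalog, roster pinned in `data/features.yaml` (15 geometric, 6 model-based, 37 first-order, 21 second-order, 35 higher-order) |
| `pettex.stats` | caliper/growth metrics, Shapiro-Wilk-gated Welch-t / Mann-Whitney comparisons, greedy |r| > 0.8 feature elimination, Bonferroni threshold, fold changes, study driver |
| `pettex.io` / `pettex.cli` | NIfTI and CSV round trips, YAML study config, `pettex` command line |

## Command line

```sh
pettex simulate --config study.yaml --out sim/ --seed 1   # phantom cohort (NIfTI + CSV)
pettex segment sim/T01_pet.nii.gz --out voi.nii.gz        # delineate the tumor VOI
pettex matrices sim/T01_pet.nii.gz --mask voi.nii.gz --out mats/
pettex extract sim/T01_pet.nii.gz --mask voi.nii.gz --out features.csv
pettex compare features_wide.csv --out report/            # filter + test + gate
pettex run-all --config study.yaml --out study/ --seed 1  # the whole chain
```

Without `--config`, `run-all` uses the built-in two-arm design (7 fine-texture
vs 7 coarse-texture phantoms). `study/summary.csv` is the per-feature report
(centers, fold change, p, test used, significance at the Bonferroni gate);
`foldchange_plotdata.csv` feeds bar plots grouped by feature category.

## Conventions

Uptake is %ID/g; voxels are isotropic (default 0.6 mm; anisotropic NIfTI is
rejected). Entropies are log base 2. Kurtosis is excess. Degenerate inputs
produce documented finite sentinels, never NaN. Texture-matrix conventions
(13 directions at Chebyshev distance 1, summation aggregation,
26-connectivity) are overridable through `MatrixConfig` / the YAML config.
Both size-zone-variability readings are computed (`glszm_szv_nu`,
non-uniformity sum; `glszm_szv_var`, variance of zone sizes); `szv_var` is
the default reported form.
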