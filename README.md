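# rededge

Red-edge feature analysis and crop classification for GF-6 WFV-like
multispectral imagery.

## The problem

The GF-6 satellite's wide-field-viewing (WFV) camera carries eight 16 m
bands, including two *red-edge* bands at 710 nm (RE1) and 750 nm (RE2) — the
spectral region where green-vegetation reflectance rises steeply and where
crop types separate best. This package implements, as a tested and reusable
pipeline, the standard methodology for quantifying what those red-edge bands
contribute to pixel-based crop classification:

1. **Band information content** — the adaptive band selection (ABS) index
   ranks each interior band *i* of a fixed analysis order by
   `I_i = σ_i / ((|r_{i−1,i}| + |r_{i,i+1}|)/2)`, its standard deviation over
   its mean absolute correlation with the adjacent bands.
2. **Class separability** — pairwise Jeffries–Matusita distance
   `JM = 2(1 − e^{−B})` from the Gaussian Bhattacharyya distance `B`,
   aggregated over all class pairs into the prior-weighted multi-class
   statistic `J_Bh = Σ_{i<j} √(P_i P_j) · JM²(i,j)` (bounded by 16 for nine
   equal-prior classes).
3. **Red-edge features** — the ten red-edge vegetation indices computable
   from GF-6 WFV reflectance (NDRE, NDVIre1/2, CIre1/2, MCARI1/2, TCARI1/2,
   MTCI), and per-band texture: eight gray-level co-occurrence matrix (GLCM)
   measures on a 3 × 3 sliding window, reduced to one layer per band by PCA
   (PC1).
4. **Feature importance** — stepwise discriminant analysis (Wilks'-lambda
   partial F-to-enter) and random-forest mean decrease Gini, compared.
5. **Twelve classification schemes** — the traditional four bands
   (R, G, B, NIR) plus red-edge spectra (A-2..A-4), red-edge/NIR texture
   (B-1..B-4) or one optimal red-edge index (C-1..C-4), each classified with
   a seeded random forest.
6. **Accuracy assessment** — confusion-matrix OA/kappa/PA/UA, per-class
   `F1 = 2·UA·PA/(UA+PA)`, and McNemar paired tests
   `χ² = (f12 − f21)²/(f12 + f21)` (1 df, significant at 3.84).

Because no public scene accompanies the methodology, the package ships a
synthetic-scene generator that plants the statistical structure the analysis
assumes — a field mosaic of nine land-cover classes whose spectra separate
mainly in the red-edge/NIR region, with class-specific texture — so every
stage is testable end to end without a satellite download. It is aimed at
agricultural remote-sensing researchers who want the full experimental chain
(or any stage of it) as a library instead of a GUI toolbox.

## Worked example

```python
from rededge.workflow import RunConfig, run_pipeline

cfg = RunConfig(out_dir="demo_run", seed=1,
                scene_width=128, scene_height=128, field_count=50,
                polygons_per_class=6, polygon_size=3, n_trees=50)
res = run_pipeline(cfg)
print("J_Bh:", res.summary["j_bh"])
print("OA%: ", res.summary["oa_percent"])
```

prints (exactly reproducible at this seed):

```
J_Bh: {'A-1': 13.7302, 'A-2': 15.5454, 'A-3': 14.8352, 'A-4': 15.6935}
OA%:  {'A-1': 73.25, 'A-2': 86.01, 'A-3': 79.84, 'A-4': 87.65, 'B-1': 71.98,
       'B-2': 74.14, 'B-3': 74.57, 'B-4': 74.57, 'C-1': 86.83, 'C-2': 86.01,
       'C-3': 86.83, 'C-4': 86.42}
```

Reading the numbers: separability rises as red-edge bands join the four-band
set (A-1 → A-4), with the 710 nm band adding more than the 750 nm band
(A-2 > A-3) — and the classification accuracies follow the same ordering:
every red-edge scheme beats the 73.25% four-band baseline, the full spectral
scheme A-4 reaching 87.65%. `demo_run/` also receives the class maps, the
per-scheme accuracy tables, the importance scores and the McNemar matrix of
all 66 scheme pairs.

The same experiment is available from the shell:

```sh
rededge run-all --seed 1 --out demo_run
rededge mcnemar --f12 6 --f21 786     # -> chi2 768.18, significant
```

## Layout

| module | responsibility |
| --- | --- |
| `synthetic_scene` | GF-6 WFV-like labeled scenes and sample polygons |
| `raster_io` | multiband TIFF / GeoJSON IO, labeled pixel extraction |
| `spectral_analysis` | ABS band ranking, JM and J_Bh separability |
| `red_edge_indices` | the ten red-edge vegetation indices |
| `texture_features` | windowed GLCM measures and texture PC1 |
| `feature_importance` | stepwise discriminant F and RF Gini importance |
| `classification` | the twelve schemes, seeded random-forest maps |
| `evaluation` | OA/kappa/PA/UA/F1 and McNemar comparisons |
| `workflow`, `cli` | config-driven orchestration and the `rededge` command |

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
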