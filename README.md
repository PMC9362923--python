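# tsvf — cultivated-land mapping from satellite image time series

`tsvf` implements a complete annual cultivated-land mapping workflow for
multi-date multispectral imagery (Sentinel-2-style band sets). It is aimed
at remote-sensing practitioners who need a small-training-sample,
interpretable alternative to deep models for cropland mapping in
heterogeneous agricultural landscapes.

## The method

For every pixel and every *parameter* p — each of the 13 spectral bands and
23 vegetation indices (NDVI, EVI, SAVI, red-edge indices, …) — the values
across the T acquisition dates form a time-series vector

    V_p = (p_1, p_2, …, p_T).

Five **vector features** summarize each V_p against the all-ones reference
vector V_0:

| feature | definition |
|---------|------------|
| Max_p, Min_p, Ran_p | extremes of V_p and their difference |
| Cos_p | cosine similarity Σ V_0·V_p / √(Σ V_0² · Σ V_p²) |
| Dis_p | squared distance Σ (V_0 − V_p)² |

With 13 bands and 23 indices this yields a 180-column feature table
(`B12_Cos`, `NDVI705_Min`, …). Features are ranked by normalized Gini
importance S_f = I_f / Σ I_f from a random forest, grouped by descending
score thresholds (0.1 > 0.04 > 0.02 > 0, nested groups A–D), and the group
with the best prediction accuracy and smallest out-of-bag (OOB) error —
each tree's OOB set is the ≈ 36.8 % of samples missing from its bootstrap
resample — is selected together with the tree count at the accuracy
plateau. A final random forest classifies the scene; confusion-matrix
statistics (OA, producer's and user's accuracy, kappa) assess it against
maximum-likelihood, SVM and neural-network baselines on identical sample
splits.

Because no public imagery ships with the package, a seeded synthetic-scene
generator produces 12-date, 13-band scenes over a six-class Voronoi mosaic
(cultivated / woodland / grassland / water / artificial / bare) with
class-specific seasonal profiles — cultivated land has the double green
peak of a winter-wheat/summer-corn rotation — patchwise substrate
brightness variability, boundary mixed pixels and additive noise.

## Worked example

```python
from tsvf.pipeline import run_reference_pipeline

res = run_reference_pipeline(seed=42)   # 256x256 scene, 12 dates, 13 bands
print(res.selected_group.label, len(res.selected_group), res.n_trees)
print(f"OA {res.oa*100:.2f}%  kappa {res.report.kappa:.4f}  "
      f"single-date baseline OA {res.baseline_report.oa*100:.2f}%")
print(res.importance.head(3)[["rank", "feature", "score"]].to_string(index=False))
```

prints

```
D 177 50
OA 99.33%  kappa 0.9920  single-date baseline OA 88.83%
 rank    feature    score
    1   IPVI_Dis 0.045381
    2  MSAVI_Dis 0.041287
    3 MSAVI2_Dis 0.035463
```

The selected group D (importance score > 0) keeps 177 of 180 features; 50
trees already sit on the accuracy plateau for this clean scene. The
vector-feature forest reaches 99.3 % hold-out overall accuracy, about 10
points above a classifier that sees only the first acquisition's band
values — the temporal trajectory, not any single snapshot, separates
off-season cropland from bare soil and in-season cropland from other
vegetation. Distance-type features of the strongly vegetation-sensitive
indices dominate the ranking.

The same workflow is scriptable from the shell:

```
tsvf simulate --seed 3 --size 128 --out scene/
tsvf extract-features --manifest scene/manifest.csv --samples scene/samples.csv --out work/
tsvf rank --features work/features.csv --seed 3 --out work/
tsvf select --features work/features.csv --importance work/importance.csv --seed 3 --out work/
tsvf train --features work/features.csv --selection work/selection.json --seed 3 --out work/
tsvf classify --manifest scene/manifest.csv --model work/model.joblib --out work/
tsvf evaluate --classmap work/classmap.tif --legend work/legend.json --samples scene/samples.csv --out work/
```

Every stage writes plain CSV/TIFF/JSON artifacts plus its resolved
configuration and seed, and re-runs bit-identically.

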