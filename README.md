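# reefchange

Coral reefs can be monitored from space: in optically shallow water, a
multispectral satellite sensor (Landsat-class, 30 m pixels, three visible
bands) sees the sea floor through the water column, and changes in per-pixel
coral cover between two image epochs can be quantified once the confounding
effects of depth, atmosphere and sun glint are removed. `reefchange`
implements that analysis end to end for scientists studying benthic habitat
change:

1. **Preprocessing** — cloud/land masking from a quality band, a water mask
   from NIR absorption, and dark-pixel subtraction of the mean deep-water
   radiance `Ls_i` per band (atmosphere + glint correction).
2. **Water-column correction** — for each visible band pair *(i, j)* the
   attenuation-coefficient ratio is estimated from calibration pixels of one
   bottom type spanning a depth range,

   ```
   a = (σ_ii − σ_jj) / (2 σ_ij),        k_i/k_j = a + sqrt(a² + 1)
   ```

   with `σ` the variances/covariance of `ln(L − Ls)`, and the per-pixel
   **depth-invariant index**

   ```
   DII_ij = ln(L_i − Ls_i) − (k_i/k_j) · ln(L_j − Ls_j)
   ```

   depends on bottom type but not on depth.
3. **Classification** — percent-cover ground truth is binarized
   (coral / non-coral), class-balanced by stratified undersampling, and an
   RBF-kernel SVM is tuned over (γ, C) by stratified cross-validation. The
   fitted model yields per-pixel coral posterior-probability maps and
   thresholded class maps, and supports three protocols: single-site,
   cross-site (train on one reef, evaluate on another) and a consolidated
   "robust" classifier pooling several training sites.
4. **Evaluation** — precision, recall, specificity, accuracy, F-measure and
   Cohen's kappa, plus ROC/AUC.
5. **Change analysis** — per-pixel transition tabulation between two epochs,
   pixel→km² conversion, percent decline and coral share of the shallow
   benthic area.

Because real survey campaigns are not redistributable, the package includes
a first-class **synthetic scene generator**: seeded two-epoch Landsat-like
scenes built from the exponential attenuation forward model
`L_i = Ls_i + a_i·r_i·exp(−f·k_i·z)`, with per-class bottom reflectances, a
smoothed depth field, a deep-water strip, cloud/land masks, sensor noise,
percent-cover survey tables and a programmed coral→non-coral conversion
between epochs. Every stage of the pipeline is tested against it.

## Worked example

```python
from reefchange.pipeline import three_site_study, run_single_site

# noiseless two-epoch site with a programmed 10 % coral loss
cfg = three_site_study(seed=0, noise_sd=0.0, change_fraction=0.10)
report = run_single_site(cfg, "A")

print(report["attenuation_ratios"]["t1"])
print(report["evaluation"]["metrics"])
print(report["change"]["percent_change"])
```

prints (abridged):

```
{'blue/green': 0.777778, 'blue/red': 0.2, 'green/red': 0.257143}
{'precision': 1.0, 'recall': 1.0, 'specificity': 1.0, 'accuracy': 1.0,
 'f_measure': 1.0, 'kappa': 1.0, 'n': 206}
10.0
```

The three ratios recover the configured attenuation ratios exactly
(0.07/0.09, 0.07/0.35, 0.09/0.35) — the closed-form estimator is exact on
noiseless single-bottom pixels — the classifier separates the noiseless DII
features perfectly, and the per-pixel change analysis reads the programmed
10 % coral loss back as a 10.0 % reduction. With the default 0.5 % sensor
noise the same quantities degrade gracefully (ratios to ~2 significant
figures, accuracies in the 0.9s).

There is also a CLI for file-based workflows:

```sh
reefchange simulate --config run.json --out sim/
reefchange train --dii sim/dii_t1.tif --ground-truth sim/ground_truth.csv --out model.pkl
reefchange classify --model model.pkl --dii sim/dii_t0.tif \
    --prob-out prob_t0.tif --class-out class_t0.tif
reefchange change --class-t0 class_t0.tif --class-t1 class_t1.tif \
    --out change.tif --report change.json
reefchange run-all --config run.json --out reports/
```

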