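# sidermap

Spatial analysis of cortical iron deposits and local neuroinflammation
in digitized serial-section histopathology.

Cortical superficial siderosis (cSS) — chronic iron deposition in the
superficial cortical layers after bleeding from leptomeningeal vessels
— is a strong predictor of intracerebral hemorrhage and cognitive
decline in cerebral amyloid angiopathy.  A central question is whether
these iron deposits provoke *local* neuroinflammation.  `sidermap`
implements the quantitative pipeline for answering it from
deep-learning object detections on adjacent sections stained for iron
(Perls' Prussian blue), GFAP (reactive astrocytes) and CD68 (activated
microglia/macrophages):

* **Co-registration with count conservation** — marker sections are
  mapped onto their iron section (affine + coarse B-spline on cortex
  masks, SimpleITK), with a global rescale so warping never changes the
  total object count; failures (Dice < 0.90) are excluded and logged.
* **Layer profiles** — object densities in artificial 1000 μm cortical
  depth layers (first five analyzed), with depth measured from the pial
  boundary.
* **Heat maps** — object counts in 500 μm × 500 μm pixels (250 μm for
  the edge-only reanalysis); pixels with more than two thirds of their
  area outside the cortex are excluded; iron burden per pixel is
  categorized very low (0–5), low (6–15), medium (16–25), high (26+).
* **Ring-coefficient model** — the marker heat map is predicted from
  the iron heat map as a weighted sum over the pixel and up to three
  concentric 500 μm rings,

  `predicted = C_pixel·d_pixel + C_ring1·d_ring1 + … ,`
  `C_pixel ≥ C_ring1 ≥ … ≥ 0, ΣC = 1.00,`

  where `d_k = s · (mean iron count in ring k)` and
  `s = median(marker | pixels with objects) / median(iron | pixels with
  objects)`.  The best combination on the 0.01 grid is found by
  exhaustive search (mean absolute per-pixel error); comparing best
  errors for 0–3 rings measures how far iron's influence reaches.
* **Statistics** — Friedman + Kendall's W, Skillings–Mack for
  incomplete blocks, Conover post hoc with Benjamini–Hochberg,
  repeated-measures ANOVA + Tukey, and linear mixed models (random
  intercepts for subject and region, age and sex as fixed effects)
  compared by likelihood ratio / AIC / BIC after Cook's-distance (4/n)
  influence filtering.
* **Synthetic cohorts** — a generator with planted ground truth
  (multifocal superficial iron, a GFAP ring response with known
  coefficients, null CD68, adjacent-section misalignment, optional
  macrohemorrhage focus), so the whole pipeline is testable without
  human material.

## Worked example

```python
import numpy as np
from sidermap import SyntheticConfig, fit_ring_model, bin_heatmap, skillings_mack
from sidermap.simulate import generate_section_triplet
from sidermap.spatial import category_profile, category_design

config = SyntheticConfig(seed=1)
sections, truth = generate_section_triplet(config, case_idx=0, region_idx=0,
                                           misalign=False)
iron, gfap, cd68 = sections
fit = fit_ring_model(bin_heatmap(iron), bin_heatmap(gfap), n_rings=3)
print("planted C*:", truth.planted_coefficients)
print("recovered: ", fit.coefficients)
print(f"error: {fit.error:.3f}  residual: {fit.residual:.3f}  pixels: {fit.n_pixels}")

pairs = []
for c in range(19):
    trip, _ = generate_section_triplet(config, c, 0, misalign=False)
    pairs.append((bin_heatmap(trip[0]), bin_heatmap(trip[1])))
design = category_design(category_profile(pairs, grouping="brain"))
print(design.mean(axis=0).round(1).to_string())
sm = skillings_mack(design.to_numpy(float))
print(f"Skillings-Mack chi2 = {sm.statistic:.2f} (df = {sm.df}), p = {sm.p:.2e}")
```

prints

```
planted C*: (0.55, 0.25, 0.15, 0.05)
recovered:  (0.52, 0.28, 0.14, 0.06)
error: 2.340  residual: 16.379  pixels: 528
very_low      2.9
low          24.2
medium       42.6
high        199.0
Skillings-Mack chi2 = 57.00 (df = 3), p = 2.57e-12
```

The exhaustive search recovers the planted ring weights to within the
0.01–0.03 a single noisy section allows, and across a 19-brain cohort
the mean GFAP count per pixel rises steeply with the pixel's iron
burden category — the planted local association, detected by the
incomplete-block rank test.

The same stages are scriptable from the shell:

```bash
sidermap simulate --out cohort/ --seed 1
sidermap run-all --cohort cohort/ --out results/
```

which writes layer profiles, ring-fit tables, exclusion logs and a
statistics summary (`results/stats.json`).

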