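# famfeed

Quantitative analysis pipeline for *C. elegans* food-familiarity
assays: ratiometric calcium imaging, pharyngeal feeding-rate
statistics, and serotonin-positive cell-count analysis, plus synthetic
generators that produce every input with known ground truth.

Worms trained on one bacterium and tested on familiar versus novel food
(condition codes HH/DD vs DH/HD: training food then test food) change
their feeding behaviour; this package implements the measurement and
inference layer such experiments need:

- **Imaging** — two-channel (cyan/yellow) FRET traces become ΔR/R via
  `R = (I₅₃₅ − I′₅₃₅)/(I₄₈₀ − I′₄₈₀) − 0.65` (bleed-through corrected),
  single-exponential photobleach normalisation `ΔR/R = R/(A·e^{−λt}) − 1`,
  10 s-binned time courses, and the signed area of ΔR/R over the first
  120 s of the stimulus.
- **Feeding** — pump counts → rates (3 × 30 s × 2 for adults, pumps/min),
  conservative two-group tests (max of Welch t and Mann–Whitney U
  p-values, two-tailed), one-way ANOVA + Tukey HSD, and the
  difference-of-differences "receptor effect" contrast
  `t = [(m₁ − m₂) − (m₃ − m₄)] / √(Σ vᵢ/nᵢ)`.
- **Cell counts** — per-experiment baseline-subtracted contrasts of
  serotonin-positive AIM/RIH counts (integers 0–3), combined across k
  experiments by Fisher's method `χ² = −2Σln pᵢ ~ χ²(2k)`.

The analysis surfaces follow a model/results pattern:
`CalciumResponseModel`, `FamiliarityContrastModel` and
`CellCountFamiliarityModel` are built from data and `.fit()` returns a
results object with estimates, uncertainties and a `summary()`.

## Worked example

Simulate a three-experiment serotonin-positive cell-count study with a
familiarity effect and run the combined analysis:

```python
from famfeed.simulate import CellCountDesign, gen_cellcount_dataset
from famfeed.cellcounts import CellCountFamiliarityModel

df = gen_cellcount_dataset(CellCountDesign(seed=1))
res = CellCountFamiliarityModel(df, comparison="HHvsDH").fit()
print(res.summary())
```

```
Serotonin-positive cell-count familiarity analysis (HHvsDH)
============================================================
per-experiment contrasts (baseline-subtracted, familiar - novel):
  experiment 1: estimate +0.360 ± 0.299 cells, t = 1.20, p = 0.232
  experiment 2: estimate +0.560 ± 0.310 cells, t = 1.80, p = 0.075
  experiment 3: estimate +1.000 ± 0.303 cells, t = 3.30, p = 0.001
Fisher combination: chi2 = 21.20, df = 6, combined p = 0.002
```

Each line is one independent experiment: the mean increase in
serotonin-positive cells after refeeding on familiar food minus the
increase on novel food (baselines subtracted per training food), with
its standard error and two-tailed t-test. Fisher's method combines the
three p-values on 2k = 6 degrees of freedom; here the combined
p = 0.002 rejects the no-familiarity-effect null.

The imaging pipeline on a simulated noisy recording (10 % transient):

```python
from famfeed.simulate import ImagingSimParams, gen_imaging_recording
from famfeed.imaging import CalciumResponseModel

rec, truth = gen_imaging_recording(
    ImagingSimParams(transient_amplitude=0.10, noise_sd=2.0, seed=1))
print(CalciumResponseModel(rec).fit().summary())
```

```
Calcium response (ratiometric ΔR/R)
===================================
frames                 1000
bleed-through          0.65
bleach fit A           0.96771
bleach fit lambda      0.00081674 1/s
bleach residual rms    0.00386
peak ΔR/R              0.1083
signed area 0-120 s   5.4639 s
```

The recovered signed area (5.46 s) sits within 3 % of the generator's
ground truth (5.61 s) at this noise level.

The same stages are scriptable from the shell:

```sh
famfeed simulate cellcounts --seed 1 --out counts.csv
famfeed cellcounts --in counts.csv --out fisher.json
famfeed simulate imaging --seed 0 --n-animals 5 --out recs/
famfeed imaging process --in recs/ --bleed 0.65 --bin 10 --window 0:120 --out proc/
famfeed run --config config.yaml   # full reproducible run with manifest
```

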