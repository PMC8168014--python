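# lhamap

Quantitative brain-wide mapping of neurons projecting to the **lateral
hypothalamic area (LHA)** from serial fluorescence sections — built for
researchers quantifying retrograde-tracing experiments (e.g. rAAV2-retro /
ZsGreen labeling in ALS mouse models) who need a tested, reproducible
version of the usual multi-tool chain (atlas registration, region
cropping, machine-learning neuron counting, QC, normalization, group
statistics, pathology scoring).

Because raw tracing images of this kind are not publicly deposited, the
package pairs every analysis stage with a synthetic-data generator that
produces serial-section cohorts with exact ground truth (region-dependent
soma densities, genotype×region projection effects, LHA atrophy, injection
deposits with dorsal backflow, autofluorescence and dendrite artifacts),
so the whole chain is testable end to end.

## What it computes

* **Atlas parcellation** — sections matched to atlas plates by named
  anatomical landmarks; affine or thin-plate-spline warps (fitted by least
  squares in both directions); per-region/hemisphere crops.
* **Neuron counting by density regression** — a random regression forest
  (Ntrees = 20, MaxDepth = 80) over a 32-channel Gaussian-derivative
  feature bank (σ = 1.0, 1.6, 3.5, 5.0) predicts a per-pixel density whose
  integral over a region mask is the count; a pixel-classification forest
  removes autofluorescence and dendrite fragments first. Accuracy is
  `100·(1 − mean |ĉ−c|/max(c,1))`.
* **Volumes and QC** — region volume = Σ cross-section area × 70 µm;
  brains excluded for oversized (>1 mm³), mislocalized, or back-flowing
  (>10% dorsal) injections, or low labeling (<25,000 neurons).
* **Normalization** — per-brain rescaling to 50,000 total neurons ("50 k
  normalization", Σ = 50,000 exactly) and LHA-atrophy compensation by the
  ratio of the brain's LHA volume to the 2.75 mm³ wild-type reference.
* **Statistics** — two-way fixed-effects ANOVA (genotype × structure) with
  Sidak-adjusted per-structure comparisons `p' = 1 − (1−p)^m` on the
  pooled residual MS; pooled-variance Student t-tests (raw or summary
  statistics); one-way ANOVA with Tukey HSD.
* **Misfolded-protein burden** — area fraction surviving rolling-ball
  background subtraction (radius 20 px) and Rényi-entropy thresholding
  (orders α→1, ½, 2 combined per Sahoo et al. 1997).

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

```python
from lhamap.stats import pooled_t_from_summary, normalize_50k
from lhamap.synth import simulate_burden_image
from lhamap.burden import burden_fraction

# human hypothalamic volumetry from printed summary statistics:
# ALS 750.8 ± 74.3 mm³ (n=72) vs controls 886.9 ± 86.5 mm³ (n=43)
t, df, p = pooled_t_from_summary(750.8, 74.3, 72, 886.9, 86.5, 43)
print(f"t = {t:.2f}, df = {df:.0f}, p = {p:.2e}")

norm = normalize_50k({"ACA": 4200, "MOs": 2100, "PIR": 700})
print(norm, "sum:", sum(norm.values()))

img, truth = simulate_burden_image(0.25, seed=7)
res = burden_fraction(img)
print(f"true fraction 0.250 -> measured {res.area_fraction:.3f}")
```

prints

```
t = -8.93, df = 113, p = 8.96e-15
{'ACA': 30000.0, 'MOs': 15000.0, 'PIR': 5000.0} sum: 50000.0
true fraction 0.250 -> measured 0.276
```

i.e. the volumetric deficit statistic |t| = 8.9 with 113 degrees of
freedom, counts rescaled so each brain contributes 50,000, and a known
25% immunostain burden recovered within the method's small positive bias
(the entropy threshold admits part of each blob's shoulder).

The full image-level pipeline runs from the command line:

```bash
lhamap run-all --out runs/demo --seed 1     # or --config config.yaml
lhamap burden --out runs/burden --seed 2 --fraction 0.05 --fraction 0.25
```

or stage by stage (`simulate`, `register`, `segment`, `count`,
`quantify`, `stats`, `report`). The numbered drivers under `analysis/`
run the same library at study scale: cohort simulation, the
counter-accuracy learning curve, the end-to-end disease-cohort pipeline,
statistical calibration (power / family-wise error), and the burden
group comparison, writing their tables under `results/`.

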