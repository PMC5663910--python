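# synquant

Quantification of activity-dependent synaptic tracer uptake in
two-channel fluorescence microscopy.

## The problem

A genetically encoded vesicular bait protein (eGFP-tagged; the *GZ*
channel) marks presynaptic boutons and their reporter expression; a
small labeled peptide tracer (*SB* channel) is captured into synaptic
vesicles during exo-endocytosis, so its accumulated fluorescence
reports cumulative vesicle cycling — a functional readout of synaptic
activity in vitro and in vivo.  Turning image pairs into population
statements requires segmenting boutons, subtracting local background,
normalizing tracer uptake by reporter expression, classifying active
synapses, aggregating per field and per animal, and comparing groups
with assumption-light statistics.  `synquant` implements that pipeline,
plus the ancillary analyses of the same assay: vesicle particle
detection, super-resolution vesicle diameter estimation, binding- and
saturation-curve fitting, uptake time series, and open-field motility
metrics.  A synthetic-data module generates ground-truth inputs for
every stage, so the whole chain is testable end to end.

## The core quantities

For each segmented bouton with mean channel fluorescences F_SB, F_GZ
and local (annular) background means B_SB, B_GZ:

* **normalized uptake index**  U = (F_SB − B_SB) / (F_GZ − B_GZ)
* **active synapse**  F_SB > B_SB + 1·SD_SB (local background SD)

Per-animal endpoints (mean uptake of chained boutons, or % active
synapses) are compared with a two-tailed two-sample permutation test on
the difference of means (exact enumeration when feasible, 10⁴ random
permutations otherwise), with Bonferroni–Holm correction across
comparisons; Cohen's d and noncentral-t power are computed from
summary statistics.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from synquant import synthetic as syn, segmentation as seg, quantification as quant
from synquant import stats as gstats

# a synthetic field: ~50 boutons on 6 axons, half of them active
params = syn.SimParams(active_fraction=0.5,
                       uptake_dist=("normal", {"mean": 0.35, "sd": 0.05}))
fov = syn.generate_fov(params, (256, 256), seed=7, noise_sd=5.0)

rois = seg.segment_voronoi(fov.gz_image)          # threshold + Voronoi split
seg.measure_rois(rois, fov.gz_image, fov.sb_image)
records = quant.records_from_rois(rois)
summary = quant.fraction_active(records)
print(f"{summary.n_synapses} boutons, "
      f"{100 * summary.fraction_active:.1f}% active, "
      f"mean uptake {summary.mean_uptake:.3f}")
print(f"ground truth: {100 * (fov.bouton_uptake > 0).mean():.1f}% active, "
      f"mean uptake {fov.bouton_uptake.mean():.3f}")
```

prints

```
45 boutons, 57.8% active, mean uptake 0.199
ground truth: 60.0% active, mean uptake 0.205
```

— the detector found the 45 generated boutons, classified the active
fraction within one bouton of the generated truth, and recovered the
mean uptake within 3% (the mean is over all boutons, inactive ones
contributing 0; with seed 7 the Bernoulli draw put 60% of boutons in
the active state).

Group comparison from per-animal values works directly on arrays:

```python
res = gstats.permutation_test([10.2, 4.1, 18.9, 5.3, 15.0],
                              [44.9, 50.1, 47.7, 46.2, 49.3])
print(res.method, res.p_value)        # permutation-exact 0.007936...
```

A `synquant` command-line tool wraps the same library for shell use
(`simulate`, `segment`, `quantify`, `stats`, `behave`, `report`); run
`synquant --help`.

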