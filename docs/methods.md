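# Methods

`synquant` quantifies activity-dependent synaptic vesicle cycling from
two-channel fluorescence images.  The assay it models uses a genetically
encoded vesicular bait protein (the eGFP-tagged variant is called GZ
here) and a small labeled peptide tracer (SB) that is captured into
synaptic vesicles during exo-endocytosis.  GZ fluorescence marks where
boutons are and how much reporter they express; accumulated SB
fluorescence reports how much vesicle cycling occurred.  This note
documents the models, algorithms, parameter choices and limitations.

## The uptake model

For a segmented bouton with mean channel fluorescences `F_SB`, `F_GZ`
and local background means `B_SB`, `B_GZ`, the normalized uptake index
is

    U = (F_SB − B_SB) / (F_GZ − B_GZ).

It is offset-invariant in each channel and scales as the ratio of the
two channels' gains, which is why acquisition gain and laser power
cancel to first order.  `U` is undefined when the reporter excess
`F_GZ − B_GZ` is non-positive; such records are marked invalid, excluded
from mean-uptake summaries, but still counted as detections.

A bouton is classified **active** when `F_SB > B_SB + k·SD_SB` with
`k = 1`, where `SD_SB` is the SD of the tracer channel over the bouton's
own background annulus (local, not field-global — the rule refers to the
synapse's surroundings).

Two group endpoints are supported, mirroring the two tissue contexts:
the percentage of active synapses per animal (flat-background cortical
fields) and the mean normalized uptake of axonally chained boutons per
animal (fields with sporadic somatic expression).  Either endpoint can
be selected for either data set via the pipeline config.

## Segmentation

**Threshold + Voronoi route.**  A Gaussian-smoothed copy of the reporter
channel (sigma 1 px) is binarized at `background mean + 2 SD`, where the
background statistics come from iterative sigma clipping (3 rounds at
3 sigma) of the smoothed image.  Seeds are regional maxima with a 3 px
minimum separation; foreground components holding more than one seed are
split by nearest-seed assignment (a Voronoi tessellation restricted to
the foreground), each cell reduced to the piece 8-connected to its seed.
Regions then pass area (4–200 px) and roundness (≥ 0.4) filters, must
have mean smoothed intensity above the threshold, and must contain a
peak at least `2.5 × 2 SD` above background, which rejects clumps of
spatially correlated noise.  With a single seed per component the
procedure reduces to connected-component labeling.

Numerical choices worth knowing:

* Thresholding the *smoothed* image matters for quantification, not just
  detection.  A raw-image threshold admits boundary pixels preferentially
  when their noise fluctuates upward, so the ROI's reporter mean is
  biased upward and the uptake ratio downward (≈ 8% at SNR 10 in our
  simulations).  Smoothing decorrelates inclusion from the raw pixel
  values and cuts the bias to a few percent.
* On noise-free images the clipped background SD collapses to ~0 and the
  threshold would sit on the PSF skirts; a relative floor of 5% of the
  smoothed dynamic range keeps regions bounded.
* Ties in seed detection are broken by scan order (row-major).

**Contrast-equalization route.**  The reporter channel is median
filtered (3 × 3), rescaled to [0, 1], and passed through tile-based
adaptive histogram equalization (tile 64 px, clip limit 0.01), which
flattens slowly varying background such as a tracer gradient.  The
equalized image is thresholded at `max(bg mean + 2.5 SD, 0.5)` — the SD
term dominates on noisy data, the absolute floor on clean data, where
equalized background is nearly constant and an SD rule degenerates.
Because equalization is a nonlinear rank-like rescaling, this threshold
lives on the equalized scale and is a free parameter of this route, not
the raw-image "2 SD" rule of the first route.  Connected components are
selected by equivalent radius (default 1–8 px).

**Per-ROI background** is the mean ± SD over an annulus 2 px away from
the ROI, 4 px wide, with all segmented ROI pixels excluded.  If fewer
than 20 annulus pixels survive, the field-global sigma-clipped
background is used instead.

**Measurement aperture.**  Channel means default to a circular aperture
centered on the ROI centroid with the ROI's equivalent radius (minimum
2 px).  The aperture is a deterministic function of the detected
geometry, so pixel inclusion does not co-select on reporter noise; this
reduced the uptake-recovery bias from ≈ 4% (mask aperture) to < 1% at
SNR 10.  The segmented mask itself is available via
`measure_rois(..., aperture="mask")`.

**Axonal chaining.**  Boutons are accepted for the chained-uptake
endpoint only when they lie along a putative axon.  Chains are grown
greedily from each unassigned ROI in both directions; the next link
minimizes `distance × (1 + turn/θ_max)` among neighbours within `d_max`
(default 5 µm in the pipeline; tests use 1.5× the generated bouton
spacing) and turning ≤ θ_max = 60°.  Chains need ≥ 3 members ("short
sequences"); all other ROIs are flagged excluded.  On synthetic fields
with 4 crossing axons ≥ 90% of chained boutons are assigned to the
correct axon; crossings are the main failure mode.

## De-trending and aggregation

When acquisition parameters varied between fields, the endpoint is
de-trended against detector gain (or gain × laser power) by ordinary
least squares *within each experimental group*; the de-trended value is
residual + group mean, so group means are preserved.  Groups with a
constant covariate pass through unchanged with a warning.  Per-animal
values are unweighted means over that animal's fields (2–5 fields per
animal in the emulated designs).

## Statistics

* **Permutation test** (two-tailed, difference of means): all
  `C(n_a+n_b, n_a)` splits are enumerated when that count does not
  exceed the permutation budget (default 10⁴) — for 5 + 5 animals that
  is 252 splits and the p-value is exact; otherwise uniform random
  label permutations with the add-one smoothed Monte-Carlo p-value
  `(1 + hits)/(n_perm + 1)`, which cannot return 0.
* **Two-sample KS test** for distributions of per-synapse fluorescence
  (asymptotic p, via scipy).
* **Bonferroni–Holm step-down** for families of comparisons (the FDR
  step-up variant is provided but is not the default).
* **Cohen's d from summaries**: group SDs recovered as `sem·√n`, pooled
  with equal weights (identical to df-weighting at equal n).  With the
  published group summaries this reproduces the printed effect sizes
  4.0 and 3.56.
* **Power** of the two-sample t-test via the noncentral t distribution
  (df = 2n−2, noncentrality `d·√(n/2)`), cross-checked against t-test
  simulation.

## Curve fits

* Binding: `y = Bmax·c/(c + Kd)` by bounded least squares; a single
  reported Kd implies unit Hill slope, so the single-site isotherm is
  the default and a free-Hill variant sits behind a flag.
  Initialization: `Bmax₀ = max(y)`, `Kd₀` from interpolated half-max.
  Adjusted R² uses p = 2 parameters.
* Saturation: `y = A·(1 − exp(−k·x))`, same machinery.
* Time series: tracer trace ÷ bouton reporter fluorescence, baseline
  frames (pre-wash-in) dropped, centered 4-sample moving average with
  truncated edges, rate = first difference ÷ frame interval (10 s
  default in the emulated recordings).
* Stack filter: per-frame 3 × 3 median prefilter, then the per-pixel
  recursion `x̂_t = g·x̂_{t−1} + (1−g)·x_t` (g = 0.8 default); the
  recursion alone leaves `(1−g)/(1+g)` of the input variance.

## Vesicle-scale analyses

Localization clouds (nm) are rendered by kernel density estimation at
4.12 nm pixel size (bandwidth defaults to the pixel size; set it to the
localization precision when known).  The grid pads the bounding box by
5 bandwidths so kernel mass is conserved within 1%.  Vesicle diameter
is estimated by an algebraic (Kåsa) circle fit refined with one
Gauss–Newton step on the geometric residuals; collinear inputs raise an
error.  Ring fitting was chosen over full-width measures of rendered
spots; with 5 nm localization noise on a 40 nm ring the fitted diameter
carries a small positive bias (< 1 nm at 200 points) because radial
noise inflates the apparent radius.

## Behavior

A pause is a maximal interval in which the barycenter stays within a
2 cm-radius circle for more than 10 s.  The circle is anchored at the
first sample of the candidate interval and the scan is greedy
left-to-right; a single excursion beyond the radius terminates the
candidate (no gap tolerance).  A centroid-anchored variant is available
but non-default.  Central-area crossings count outside→inside
transitions of a 19 × 11 cm rectangle centered in the 38 × 22 cm cage.

Frame-exact recovery of pause boundaries is only well defined when the
animal moves more than the confinement radius between frames; the
recovery tests therefore use a fast walk (15 cm/s at 5 fps).  At
realistic speeds the detected onset can precede the scheduled onset by
the time the approach path lingers within the radius — a property of the
definition, not an implementation artifact.

## Synthetic data: what it does and does not emulate

Fields of view are rendered as isotropic Gaussian peaks (sigma 2 px,
configurable; a typical confocal bouton at 63× is 2–4 px) along smooth
random polylines, with uniform arc-length spacing, jitter, and an
enforced minimum separation of 4·sigma so ground truth is unambiguous.
The tracer channel adds a radially decreasing background gradient
emulating diffusion from a perfusion site; analysis fields are assumed
to sit on the flat portion of that profile.  Reporter amplitudes and
uptake are drawn per bouton from configurable distributions (defaults:
amplitude ~ N(100, 15) a.u., uptake ~ N(0.30, 0.06) clipped at 0); a
configurable fraction of boutons is inactive (uptake exactly 0).  Noise
is additive Gaussian (read-noise proxy) — sufficient to exercise the
1 SD / 2 SD threshold rules; gain and laser power enter as pure
multiplicative factors.

Not emulated: 3-D structure and optical sectioning, photobleaching,
drift, Poisson shot noise (available via config in principle but not
default), somatic fluorescence, and spatially varying PSFs.  Passing
recovery tests on these fields therefore shows the estimators are
correct under the stated forward model, not that they are robust to
every property of real tissue.

## Problem sizes in the reproduction script

`scripts/acceptance.py` runs scaled-down in-silico replicas: 5 animals
× 3 fields per group for the active-synapse experiment, 6 × 3 for the
uptake experiment (the published designs used 2–5 and 3 fields/animal),
20 fields per algorithm for detection scoring, 428 vesicles, 100-odd
curve fits, 1000 null permutation simulations.  Vesicle diameters are
drawn by stratified inverse-CDF sampling of the moment-matched
lognormal so a 428-vesicle sample represents the stated population for
any seed.  Everything derives from the `--seed` argument.

## Known limitations

* The Voronoi seed rule (regional maxima on the smoothed image) is a
  declared choice; the original description names the tessellation but
  not the seeding.
* `segment_contrast` merges boutons closer than ~2·sigma whose skirts
  survive equalization; only the radius filter protects against it.
* The chaining heuristic is greedy and can switch axons at crossings.
* Effect sizes from summaries assume equal-n groups (true for all
  emulated designs).
* The uptake index inherits ratio noise when reporter excess is small;
  records near the validity boundary are noisy even when valid.
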