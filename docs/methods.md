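# Methods

This note records the models, conventions and numerical choices behind
`oomorph`, what the synthetic generator does and does not emulate, and the
problem sizes the packaged experiments use.

## Phantom model

A phantom oocyte is three nested closed boundaries — ooplasm, PVS outer,
ZP outer — each a (super)ellipse radius function optionally perturbed by a
low-order Fourier series:

    r(θ) = r_base(θ; a, b, rotation, exponent) · (1 + Σ_{k=2..5} c_k cos kθ + s_k sin kθ)

Low-order modes give realistic sub-unity circularity without
self-intersection. Labels are rasterized by painting outer to inner
(ZP, then PVS, then ooplasm) at pixel centers (0-based, row-major), which
makes the label image single-valued and guarantees nesting. The grayscale
image assigns each class a mean intensity (ooplasm 95 < ZP 120 <
background 190 < PVS 235 by default) plus i.i.d. Gaussian noise (sd 6).
There is no partial-volume blending and no absolute size scale: clinical
micrographs carry no pixel pitch in our setting, so all downstream features
are dimensionless and phantoms are calibrated on ratios only.

Default geometry (ZP outer semi-axes 88 × 84 px, ZP thickness 16 px, PVS
outer = 0.949 × ZP inner, ooplasm = 0.90 × PVS outer, in a 256² image) was
calibrated once so that population means of the ratio features match real
MII cohorts: ooplasm-vs-ZP major-axis ratio 0.70, ooplasm-vs-PVS area ratio
0.81, ooplasm-vs-PVS major-axis ratio 0.90.

Per-oocyte variation has deliberately independent latent factors:

- overall size jitter (relative sd 0.05) and shared elongation jitter
  (sd 0.018), common to all three boundaries;
- a small isotropic ooplasm scale jitter (sd 0.012);
- an anisotropic jitter on the ooplasm major axis only (sd 0.025) — real
  compartments are not exactly similar ellipses;
- superellipse "boxiness" of the ooplasm (exponent 2 ± 0.25, clipped to
  [1.6, 2.6]), which moves enclosed area at nearly fixed axis lengths;
- independent Fourier coefficients per boundary (RMS radial amplitude
  1.2 px) and small center offsets (≤ 2 px).

With boundary noise and elongation jitter both zero the generator enters an
analytic-ellipse mode (boxiness forced to exponent 2), so every boundary is
an exact ellipse — the basis of the raster-accuracy oracles.

**What the phantom does not emulate.** Photorealistic texture, polar
bodies, cumulus debris, dysmorphisms, partial-volume edges, uneven
illumination. Two measurable consequences: phantom solidity stays ≈ 1.000
(low-order Fourier perturbations keep boundaries convex) and ZP circularity
sits near 0.99, whereas real cohorts show ≈ 0.84 — real contours are far
rougher than the phantom's. Tests passing on phantoms therefore validate
the measurement and modeling machinery, not segmentation robustness to real
micrograph artefacts.

## Cohort datasets and the outcome process

Patients receive a clinic (5 sites, uniform), an integer age
(N(36, 4.5²) clipped to [21, 45]) and 1–3 retrieval cycles
(P = 0.84/0.13/0.03, mean 1.19). Cohort sizes follow 1 + NegBin(2.434,
0.292) — mean ≈ 6.9, sd ≈ 4.6 oocytes per cycle. Outcomes are Bernoulli
draws from a logistic model on the oocyte's *true* (analytic) features;
each record stores its true probability so the Bayes AUC of any experiment
is computable exactly.

Outcome terms are per-standard-deviation log-odds on standardized features,
either linear (`coef · z`) or quadratic (`coef · z²`). The quadratic form
encodes an optimum with a tolerated band — the pattern seen in real
cohorts, where developmentally competent oocytes occupy *narrower* feature
ranges than arrested ones. The default model uses linear terms (age −0.5,
ooplasm roundness +0.6, ooplasm-vs-PVS area ratio −0.5, cohort size +0.3;
intercept −0.45, prevalence ≈ 0.40, signs matching the observed group
differences in real cohorts). The driver-recovery model
(`recovery_outcome_model`) uses age −0.8 linear plus quadratic penalties
(−0.7) on roundness and area ratio, intercept 0.9 (prevalence ≈ 0.44).
Standardization constants are the default-phantom population values
(roundness 0.9337 ± 0.0387, area ratio 0.8091 ± 0.0464), frozen at
calibration time.

**Why quadratic drivers for the recovery experiment.** The direct
least-squares conic fit ties measured area to the fitted axes,
A ≈ (π/4)·L_maj·L_min, to ~10⁻⁴ for every smooth star-convex shape we
tested. Measured ooplasm geometry therefore has two effective degrees of
freedom, and roundness (≡ L_min/L_maj) and the area ratio (≡ major ratio ×
minor ratio) are fixed 45°-rotated directions in that plane, interleaved
with the plain axis-ratio features. Any *linear* combination of the two
drivers is geometrically equivalent to a single axis-ratio direction, so a
tree model can always route the signal through an axis ratio and Shapley
credit never concentrates on the named drivers. Deviation-from-optimum
(quadratic) signals penalize rotated proxies quadratically in the
correlation, which makes the named drivers identifiable — and is the more
faithful model of the biology. Residual run-to-run variability remains
because aspect ratio is exactly the reciprocal of roundness (a structural
duplicate whose credit share is split).

## Measurement conventions

- **Filled outer contour.** Each region is measured on the area enclosed by
  its outer boundary (PVS = ooplasm ∪ PVS band; ZP = whole oocyte). The
  standard inter-region ratios (≈ 0.70, ≈ 0.81 above) only live in (0, 1)
  under this convention; band-only measurement would not produce them.
- **Sub-pixel contours.** The binary region mask is smoothed with a
  Gaussian (σ = 1.5 px) and the 0.5 level-set polygon extracted; perimeter
  is the polygon arc length. A raw pixel-edge perimeter overestimates arc
  length by ~6% on a disk and depresses circularity; the smoothed
  iso-contour brings area within 0.3%, perimeter within 0.1% and axes
  within 0.2% of analytic values on rasterized ellipses (tolerances used in
  tests: 1.5%, 2%, 1%).
- **Ellipse fit.** Direct least-squares conic fit to the contour polygon;
  axes are the fitted semi-axes doubled, with L_maj ≥ L_min enforced.
- **Degenerate inputs.** Regions under 50 px are refused (descriptor noise
  dominates); absent regions raise; descriptor values marginally above 1
  from raster effects are reported unclamped.
- **Hull area** enters solidity only and is never ratioed between regions.

## Segmentation baseline

Pixels are classified to the nearest of four intensity levels on the *raw*
image (the phantom has no partial-volume edges, so smoothing before
classification only blurs thin PVS bands; a σ = 0.5 px smoothing is used
for level *estimation* via multi-Otsu when levels are not supplied, under
the brightness ordering ooplasm < ZP < background < PVS). Topological
repair keeps the largest non-background component with holes filled as the
oocyte, the largest filled ooplasm component inside it, rebuilds the PVS
disk as fill(ooplasm ∪ PVS pixels), and assigns the remaining shell to the
ZP — so stray PVS pixels inside the ooplasm are reassigned and nesting is
guaranteed. Fewer than four separable intensity modes (e.g. a blank image)
or an empty repaired class raises a segmentation error. On noisy default
phantoms the per-class IoU is ≈ 0.9995 (ooplasm), 0.998 (PVS), 1.000 (ZP).
This baseline exists to exercise the pipeline at desk scale; it assumes
intensity-banded images and is not a micrograph segmenter.

## Splitting, training, ensembling

Patients are shuffled by seed and assigned greedily to the split with the
largest remaining oocyte deficit — fractions stay within ~2 percentage
points of 60:20:20 even for heavy-tailed cohort sizes, and a single patient
holding more oocytes than the largest fraction is rejected as infeasible.
LightGBM defaults: 400 rounds, learning rate 0.05, 31 leaves, minimum 20
samples per leaf, early stopping after 50 rounds on the validation split,
`deterministic=true`, one thread (hyperparameters are this package's own
choices). Optional per-clinic minority oversampling (seeded) is off by
default. The ensemble rule is a weighted mean of probabilities — the
minimal-assumption default, chosen because no canonical combination rule
exists for merging a feature-based and an image-based probability; weights
are configurable.

## Evaluation statistics

AUC is computed from midranks (ties count half) and equals the
Mann–Whitney probability. The paired DeLong test uses placement values:
the covariance matrix of the two models' positive- and negative-side
placements gives the variance of the AUC difference; identical score
vectors short-circuit to p = 1, and zero variance with unequal AUCs raises
rather than dividing by zero. Welch's t-test uses the unequal-variance
statistic with Welch–Satterthwaite degrees of freedom. PCA standardizes
features, drops constant columns with a warning, and keeps the fewest
components reaching the target cumulative explained variance (default
0.95). No multiple-testing correction is applied across subgroups or
ablations; raw two-sided p-values are reported.

Subgroup analysis bins integer ages as <30, 30–34, 35–37, 38–39, ≥40, with
an optional exclusion of oocytes older than a cutoff (43 in external-
validation style analyses). A subgroup is nested inside the overall set, so
its AUC and the overall AUC are not independent; the default "nested"
comparison estimates var(AUC_sub − AUC_all) as var_sub − var_all (floored
at 5% of var_sub), the natural estimate for nested samples, and an
"independent" variant (variance sum) is available. Both carry the nesting
caveat; single-class subgroups report sensitivity/specificity with AUC
undefined. Region-wise ablations drop every column *involving* a region
(descriptors plus relative/cohort columns built from its measures);
"cohort" drops the 24 cohort columns; "clinical" drops age and cohort size.

## Shapley attribution

Attributions are exact interventional Shapley values in logit space. For a
tree and an (explained, reference) point pair, each split either sends both
points the same way or splits them; reaching a leaf then requires a fixed
set U of features taken from the explained point and a disjoint set V from
the reference, and the Shapley value of the leaf indicator has the closed
form +w·(|U|−1)!|V|!/(|U|+|V|)! for features in U and
−w·|U|!(|V|−1)!/(|U|+|V|)! for features in V. Summing over leaves, trees
and reference rows gives exact attributions at one tree walk per triple
(JIT-compiled; coalition membership is a 64-bit mask, capping explainable
models at 64 features). The base value is the mean model logit over the
reference set (default: the training split, capped at 1000 seeded rows),
and base + Σφ = f(x) holds to machine precision — verified in tests against
brute-force enumeration of all 2^f coalitions with the same
marginal-expectation value function. Waterfall exports order features by
|attribution| and fold the tail into an "other" term that preserves the
additivity identity. MASV rankings sort descending with ties broken by
feature name.

## Problem sizes in the packaged experiments

The driver-recovery study uses 500 patients (≈ 4000 oocytes) at seed 7,
MASV over the test split against a 100-row seeded reference; the
segmentation benchmark scores 100 rendered phantoms; the DeLong null
calibration runs 1000 simulations of 100 samples; the pipeline demo runs
300 patients end to end in well under a minute on one CPU. Analytic
(truth-geometry) measurement is used for cohort-scale feature extraction;
the raster path (render → segment → measure) is validated separately on
smaller image sets and available end to end via `use_predicted_masks`.

## Known limitations

- The feature enumeration is the natural 48 + 2 = 50 columns; published
  mask-model feature lists of 47 cannot be reconciled exactly with any
  natural enumeration, so the full set is kept and any named subset can be
  dropped via configuration.
- The baseline segmenter presumes the phantom's intensity-band structure.
- Interventional Shapley values on strongly correlated features split
  credit across functionally equivalent transforms (e.g. aspect ratio vs
  roundness); rankings should be read at the level of feature families.
- The ensemble's second probability must come from elsewhere (the image
  branch of a two-model workflow is out of scope here); any probability
  vector of matching length is accepted.
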