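# Methods

## Stain model

Brightfield chromogens follow Beer–Lambert absorption, so per-channel
optical density `OD_c = −log10(max(I_c, 1) / I0)` is the linear domain for
stain arithmetic. The background intensity `I0` defaults to 255 per
channel (configurable); zero intensities are floored at 1 so OD stays
finite, and pixels brighter than background clamp to OD 0. Unmixing solves
`M·c = od` per pixel, where the columns of `M` are unit stain vectors —
the widely published H-DAB constants, H ≈ (0.65, 0.70, 0.29) and
DAB ≈ (0.27, 0.57, 0.78) after normalization, with the residual vector
their normalized cross product. These are conventional stand-ins, exposed
as configuration, not claims about any particular scanner; negative
concentrations are clamped to zero (physical nonnegativity). Collinear
bases raise `SingularBasisError`. Whole-slide pyramidal formats, stain
vector auto-estimation and color normalization are out of scope.

## Nucleus detection

Nuclei come from the hematoxylin OD channel. The nuclear mask is the
`od_threshold` (default 0.1 OD) level set of the image after light
denoising (`edge_sigma_um = 0.3`); a heavier Gaussian
(`smoothing_sigma_um = 1.5` µm) is applied only to the distance-transform
landscape whose h-maxima (`h_minima_um = 0.5` µm) seed the watershed that
splits touching nuclei. Separating the two scales matters: thresholding a
heavily blurred image dilates the apparent nuclear boundary by 2–3 px,
which would swallow the 1 µm perinuclear band being measured. Candidate
nuclei are kept when their area lies in [15, 400] µm² and their mean raw
OD reaches the threshold. All defaults are explicit configuration, chosen
to be reasonable for ×40-scanned breast tissue (0.25 µm/px typical;
synthetic fixtures use 0.5 µm/px for speed), and make no claim of
equivalence to any specific interactive tool's defaults.

## Ring and cytoplasm geometry

For every background pixel the *exact integer squared* Euclidean pixel
distance to each nucleus mask is computed (per-nucleus windowed distance
transforms, windows padded past the cytoplasm radius so windowing is
lossless). The pixel is owned by the nearest nucleus; exact ties go to the
lower label id (first-writer-wins over ascending labels), which is
deterministic and reproducible by a brute-force per-pixel oracle — the
test suite asserts pixel-exact agreement on random configurations. The
perinuclear ring is the owned band at distance ≤ 1 µm from the nucleus
boundary, the cytoplasm the band at ≤ 5 µm; both exclude all nucleus
pixels, so the ring of one cell never touches another cell's compartments
and ring ⊆ cytoplasm whenever the widths are ordered. The ring is taken
*outside* the nuclear mask (an expansion "around the nucleus"); measuring
pixel-thin bands straddling the boundary is possible by changing the
widths but is not the default. Micron thresholds are compared directly
against exact distances — no dilation counting — so geometry is
resolution-independent.

Distances are compared as `d² ≤ (w / pixel_size)²` with `d²` integer, so
results carry no floating-point ambiguity at band boundaries.

## Positivity call

`positive ⇔ (ring mean DAB OD ≥ threshold) AND (ring mean ≥ ratio ×
cytoplasm mean)`, with empty-ring cells negative. The threshold (default
0.3 OD) has no canonical published value — in practice it is set per
cohort after QC; `plot_ring_od_histogram` supports that manual step. The
ratio criterion (default 1.0) encodes the qualitative goal of separating
an intense perinuclear rim from diffuse cytoplasmic staining: a diffuse
cell's ring carries no enrichment over its cytoplasm, so requiring
ring ≥ cytoplasm rejects it regardless of absolute intensity. Setting
`ratio = 0` recovers a pure intensity threshold.

## Tumor/stroma classification

A random forest (100 trees, fixed seed, out-of-bag accuracy reported) over
eight morphology + stain features: nucleus area, mean nuclear hematoxylin
OD, mean DAB OD in nucleus/ring/cytoplasm, eccentricity, solidity, and
nucleus:cell area ratio. Training annotations below 10 per class trigger a
warning (the practical minimum before a classifier is worth accepting);
single-class training is an error. Hyperparameters are not tuned — the
separability of round epithelial vs elongated stromal nuclei carries the
problem.

## Core and patient scores

`percent_positive = 100 · positive tumor cells / tumor cells` per core;
stromal cells enter neither numerator nor denominator. QC: cores with
fewer than 100 tumor cells are removed — read strictly, so a core with
exactly 100 cells is retained. QC filtering happens *before* replicate
averaging (the alternative order is defensible; this one is documented and
fixed). Patients with no QC-passing core are excluded with a logged
reason. Cohorts are dichotomized at the median with `high ⇔ value >
median` — ties at the median are low — and an external cut-point can be
supplied to transfer a discovery cohort's threshold onto a validation
cohort.

## Gene signature

Probe-level matrices are collapsed to genes by mean (median/max
configurable). Genes are ranked by the signal-to-noise ratio
`(mean_low − mean_high) / (sd_low + sd_high)` with per-group sd floors of
`max(0.2·|mean|, 0.2)` — the canonical ranking metric for this style of
analysis; a Welch t-statistic is available as an alternative. The top of
the ranking is genes *upregulated in the low group*, the direction that
defines a poor-prognosis signature; the top 25 form the default
signature. Sample score = −Σ signature-gene expression (strictly
antitone: raising one gene by δ lowers that sample's score by exactly δ).
Absolute scores are platform-dependent, so each dataset is split at its
own median and cross-dataset score comparisons are never made; the
package accepts any externally supplied gene list in place of a derived
one.

## Survival statistics

Times are months. Kaplan–Meier and Cox fits delegate to lifelines (Efron
tie handling for Cox — the standard default; ties method is not a tunable
here). The log-rank statistic is computed directly from risk tables —
`(O − E)² / V` with the hypergeometric variance — because the O/E
(Mantel–Haenszel) hazard ratio `(O₁/E₁)/(O₂/E₂)` and its log-scale CI
(`se = √(1/E₁ + 1/E₂)`) are not exposed by library fitters; the test
suite cross-checks the statistic against both lifelines and a brute-force
oracle. Both log-rank and Cox hazard ratios are reported since published
figures vary in which they quote. Covariates are coded as in clinical
practice for this setting: age category (<40, 40–49, 50–59, >60), T stage
(1–4), nodal status (negative/positive), dummy-coded against first
levels. The interaction likelihood-ratio test compares Cox models with
and without group × modifier terms, `2·Δloglik ~ χ²(df = #interaction
parameters)`; a violated nested-likelihood ordering (beyond 1e−6) raises
rather than silently truncating. Spearman correlations use average-rank
ties, with Benjamini–Hochberg adjustment over the upper triangle only and
constant variables flagged as undefined rather than adjusted. Robust
z-scores are `(x − median)/(1.4826·MAD)` per row/column; zero-MAD slices
are flagged and zeroed. All p-values are two-sided; significance handling
belongs to the caller.

## Synthetic data: what it emulates, and what it does not

**Cores.** Nuclei are ellipses placed by rejection sampling with a minimum
center spacing wide enough that 5 µm cytoplasm halos never overlap
(an optional touching-pairs mode plants overlapping nucleus pairs to
exercise the watershed). Tumor nuclei are near-circular (axis ratio
0.85–1.0, eccentricity < 0.6), stromal nuclei elongated (ratio 0.30–0.45,
eccentricity > 0.85); radii are 3–4.5 µm. Defaults: 200 tumor + 50
stromal cells, 40% perinuclear-positive and 30% diffuse among tumor
cells, hematoxylin OD 0.7, ring OD 0.8, diffuse OD 0.5, concentration
noise sd 0.02, 0.5 µm/px. Perinuclear cells get a ~1 µm DAB annulus just
outside the nucleus over a faint (0.12 OD) cytoplasmic halo. Diffuse
cells get cytoplasmic DAB that ramps linearly from zero at the nuclear
boundary to full intensity 2 µm out: diffuse staining carries no
perinuclear accumulation, which is precisely the contrast the ring/ratio
rule keys on — a perfectly uniform cell, where ring mean equals cytoplasm
mean to within noise, is a knife-edge case the ratio rule cannot decide
and the real assay does not present. The image is composed through the
same stain basis the pipeline unmixes with (a perturbed-basis robustness
mode is available via `SyntheticCoreSpec.basis`) and quantized to 8-bit
RGB.

Passing end-to-end tests on these images therefore demonstrates the
geometry, measurement and scoring logic, *not* robustness to real-tissue
hazards: out-of-focus regions, necrosis, folds, overlapping cells,
stain-vector drift, or chromatin texture. Those remain the user's QC
burden, as they are with any digital-pathology workflow.

**Cohorts.** Latent groups of equal size; signature genes shifted by
`effect_size` (default 1 sd) in the poor-prognosis group, all else
standard normal — no correlation structure, batch effects or
platform-specific intensity distributions. Survival is exponential under
proportional hazards (baseline 0.02 events/month ⇒ median ≈ 35 months in
the poor-prognosis group; `hazard_ratio` = 0.4 by default for the
high-score group). Censoring is independent `U(0, τ)` with τ solved by
root-finding so the expected censored fraction matches the target
(default 30%); the realized rate stays within ±5 points over seeds.

## Problem sizes and numerics

Default test and acceptance runs use 200–250-cell cores at 0.5 µm/px
(≈ 800×800 px), cohorts of 300 patients × 200 genes, 100–200 simulation
replicates for calibration/power/coverage checks, and 1,000-pair stain
round-trips — sizes chosen so the full suite completes in well under a
minute per stage while leaving Monte-Carlo noise far from the asserted
margins. Stain round-trips are exact to ~1e−15; ring geometry is
pixel-exact by construction; detection-to-truth matching uses Hungarian
assignment with an 8 px gate. Every stochastic stage takes an explicit
seed and is bit-reproducible.

## Known limitations

- Nucleus segmentation is classical (threshold + watershed); heavily
  textured or crowded real nuclei will fragment or merge where a learned
  segmenter would not. The geometry downstream is agnostic to where the
  labels came from, so an external label map can be substituted.
- The perinuclear ring is measured outside the nuclear mask; staining
  that sits just *inside* the segmented boundary (or boundary placement
  error of the segmenter itself) shifts ring means.
- The O/E hazard-ratio estimator and the Cox MLE agree only
  asymptotically and for modest effects; both are reported, and they
  should not be mixed across analyses.
- Signature scores are sums of log-scale intensities and are only
  meaningful relative to a dataset's own median; no cross-platform
  calibration is attempted.
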