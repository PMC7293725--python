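# Methods

## Scope and model

`steatoquant` quantifies macrovesicular steatosis as an area fraction:
the percentage of tissue-section area occupied by lipid vacuoles. The
underlying image model is minimal and deliberately stain-agnostic: on a
luminance rendering of an H&E photomicrograph, parenchyma is mid-gray,
unstained structures (fat vacuoles, vessel lumina) are bright, and the
empty slide around the specimen is brightest of all and connected to the
image border. No colour deconvolution, no learned segmentation — every
step is a deterministic, auditable rule, so two runs on the same image
always give the same number.

### Denominator

"Percentage of steatosis" is read as a fraction of parenchyma. Tissue is
defined as the complement of border-connected bright area: bright
regions *enclosed* by tissue (the vacuoles being measured, and vessel
lumina) count in the denominator, the white slide margin does not. The
alternative — normalising by whole-image area — would make the readout
depend on how much empty slide the photographer included.

### Per-slide threshold (the adaptive gray filter)

Staining intensity varies widely between slides, so the fat/stroma
threshold is derived from each slide's own intensity distribution over
tissue pixels:

* If the distribution is genuinely bimodal, Otsu's criterion separates
  the stain mode from the bright mode. Bimodality is accepted when the
  two Otsu classes are separated by more than twice the sum of their
  spreads and the minority class holds at least 0.5% of pixels.
* Otherwise (a slide with little or no fat is effectively unimodal, and
  Otsu would split the stain mode in half, flooding the candidate mask
  with noise) the threshold falls back to the `bright_quantile` (default
  0.85) quantile: only the extreme bright tail remains candidate, and
  the sub-resolution noise it produces is removed by the minimum-area
  rule downstream.

A useful consequence of building both branches from the distribution
itself: the rule is scale-equivariant, so a globally dimmer exposure of
the same slide yields the same candidate mask. A constant-intensity
slide has no contrast to threshold and is rejected as degenerate rather
than quantified.

### Shape-based region filtering

Candidate bright regions inside tissue are classified with three
exclusion rules in fixed precedence (first match wins), because real
lumina often violate several criteria at once and stable bookkeeping
matters for audit:

1. **Large** (`area > max_vacuole_px`): vessel-scale regions.
2. **Shape** (`circularity < 0.4` or `solidity < 0.85`): elongated or
   ragged regions. Circularity is 4π·area/perimeter² with the perimeter
   counted as exposed 4-neighbour pixel edges ("crack" perimeter). On
   this metric a digitised disk scores ≈ π²/16 ≈ 0.62 regardless of
   radius, while a dilated curvilinear structure scores far below 0.4 —
   the 0.4 cutoff sits in the wide gap between the two. The crack
   perimeter was chosen over smoother estimators precisely because it is
   exactly reproducible by an independent brute-force implementation.
3. **Border** (touching non-tissue or the image edge, on by default):
   a bright region at the specimen boundary cannot be distinguished from
   background reliably.

Regions below `min_vacuole_px` (default 30 px) are dropped as noise
before classification. All defaults are sized for 512×512 images with
vacuole radii of ~4–16 px; at other magnifications the area bounds
should be rescaled quadratically with the pixel pitch, which is why
`pixel_size_um` is carried as optional metadata.

## Synthetic slides

The generator renders the image model directly: a pink tissue rectangle
(RGB (225, 148, 168), luminance ≈ 0.68) inside a 12 px white margin,
near-circular vacuoles (ellipses, axis ratio ≤ 1.3) in near-white
(246, 246, 248), optional vessel-like structures drawn as persistent
random walks dilated to a width of `vessel_scale/15` px, and i.i.d.
Gaussian pixel noise (default SD 5 of 255) inside the tissue. Ground
truth masks for fat, vessels and tissue are returned with the image, and
`achieved_fat_fraction` is exactly the rendered mask ratio.

Vacuoles are placed without overlap and with a minimum 1 px gap so that
no two merge into one connected component (a merged pair would fail the
circularity rule and corrupt recovery measurements). Placement is by
seeded rejection sampling up to a hard cap of 10⁵ attempts. Random
sequential placement of gapped disks jams near 47% coverage — and a
randomly packed base caps even subsequent optimal filling at ~53% — so
two refinements keep high fractions feasible: when sampling stalls (400
consecutive rejections) placement switches to a clearance-guided mode
that drops circles at the widest remaining free spots (via a distance
transform of free space, widest first), and targets above 50% skip the
random phase entirely and pack greedily from the start, reaching ~61%.
This mimics, loosely, the dense coalescing vacuole fields of severe
steatosis. If the target is still missed by more than 0.02 the generator
raises a feasibility error carrying the achieved fraction instead of
silently under-delivering.

Vessels are placed before vacuoles; their dilated-random-walk geometry
guarantees low circularity and solidity, so the separation between
"vacuole" and "vessel" is achievable by the stated rules rather than by
tuning. What the generator does **not** emulate: nuclei, sinusoids,
inflammatory infiltrate, staining gradients, JPEG artefacts, uneven
illumination, or out-of-focus blur. Passing the recovery tests therefore
demonstrates correctness of the measurement pipeline under the stated
image model, not robustness to every real-world acquisition artefact;
on real material the config thresholds are the intended adjustment
points.

## Synthetic cohorts

The cohort generator emulates a four-group pre/post design (default
group sizes 12/9/5/5, the realistic scale of a large-animal study):
per animal and variable, `pre ~ Normal(pre_mean, pre_sd)` and
`post = pre + group_shift + Normal(0, pre_sd)`, floored at zero for the
inherently non-negative panel (lipids, enzymes, bilirubin, oxidative
markers, steatosis %). The default variable panel covers triglycerides,
total/HDL/LDL cholesterol, AST, ALT, GGT, alkaline phosphatase,
bilirubin, MDA, carbonyls and steatosis percentage, with pre-means and
shifts chosen as plausible values for diet-induced steatosis with
partial reversal in the groups that discontinue the diet. Within-animal
correlation across variables is not modelled; each (animal, variable)
pair is drawn independently, which is sufficient for exercising the
per-variable paired workflow.

## Assay arithmetic

* **MDA + 4-HDA**: the chromophore read at 586 nm has no universally
  agreed molar absorptivity, so quantification goes through a linear
  standard curve (absorbance = slope·concentration + intercept, ordinary
  least squares over ≥ 2 calibrators at ≥ 2 distinct levels);
  back-calculation is `dilution · (A_net − intercept)/slope`. A
  back-calculated value within 1e−9 below zero is clamped to 0 and
  flagged; anything more negative is an invalid sample.
* **Carbonyls**: direct Beer–Lambert inversion, c = A_net/(ε·l) with
  ε = 22,000 M⁻¹cm⁻¹ for the DNPH derivative, converted as
  1 mol/L = 10⁶ nmol/mL and normalised per mg/mL of total protein.
* Blank subtraction happens inside the calculators so plate files keep
  raw readings; negative net absorbance is an error, not a silent zero.

## Statistical workflow

Paired pre/post comparisons per (group, variable) cell: the paired
differences are gated through Shapiro–Wilk at α = 0.05 — normal →
paired Student t; otherwise → Wilcoxon signed-rank. Wilcoxon details,
all recorded in the result object: zeros dropped (Wilcoxon's original
treatment), tied magnitudes get average ranks, the exact null
distribution is used for n ≤ 25 when magnitudes are tie-free, and a
normal approximation with continuity correction otherwise. All tests
are two-sided. An all-zero difference vector returns p = 1 with a
degenerate flag instead of failing, and cells with n < 3 are reported
as skipped. Raw per-variable p-values are reported by default;
Benjamini–Hochberg adjustment is available behind a flag but off, to
match the per-variable reporting style of small pre/post studies.

Correlation follows the same gate: Pearson when both marginals pass
Shapiro–Wilk, Spearman otherwise. Method agreement (pathologist vs.
program) reports the mean and SD of the paired score difference and the
correlation of the two methods' percent-change vectors when pre/post
pairs are available (raw scores otherwise) — percent change is the
effect currency of the workflow because it is invariant to each method's
own scale offset.

## Numerical choices and degenerate inputs

* Connectivity is 8-connected throughout (candidates and background);
  labels are assigned in raster order.
* Candidate pixels are *strictly above* the threshold.
* Constant slides, all-white slides, empty tissue masks, zero-variance
  vectors, n < 3 samples, and zero `pre` values in percent change all
  raise typed errors rather than returning silent defaults.
* All generator randomness comes from one `numpy` Generator seeded per
  call; there is no global random state anywhere in the package.

## Problem sizes in the verification suite

The acceptance checks run at the scale the defaults are tuned for:
512×512 slides, 20 seeds per fat level at 5/15/30/45/60%, 20 vessel-rich
slides, 100 random ≤ 64×64 images for exact oracle comparison, all 2ⁿ
sign patterns for n = 3..10 for Wilcoxon exactness, 1,000 random assay
samples, and 100 seeded cohorts each for power and size.

## Known limitations

* Microvesicular steatosis (sub-resolution droplets) is below the
  minimum-area rule by design; the tool measures the macrovesicular
  fraction only.
* Vacuoles that genuinely coalesce into non-convex clusters in real
  tissue will be partially excluded by the shape rule; the measured
  fraction is then a lower bound.
* Agreement analysis assumes both methods scored the same sections; no
  sampling-error model for within-liver heterogeneity is included.
* The normality gate at n = 5 has little power; for the smallest groups
  the test choice effectively defaults toward the t-test unless
  departures are gross. This mirrors standard practice rather than
  fixing it.
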