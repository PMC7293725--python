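# steatoquant

Computer-assisted quantification of macrovesicular hepatic steatosis on
H&E photomicrographs, with the surrounding analysis workflow of a
two-biopsy (pre/post intervention) animal study: synthetic ground-truth
data generation, oxidative-stress assay calculators, and paired
nonparametric statistics.

## The problem

In H&E-stained liver sections, lipid vacuoles are unstained: they appear
as bright, round holes in pink parenchyma. The standard readout —
a pathologist's visual estimate of the percentage of section area
occupied by fat — is semiquantitative and systematically biased upward,
because veins, arteries and sinusoidal spaces are also bright and easily
folded into the impression of "white area". `steatoquant` measures the
steatosis area fraction

```
steatosis % = 100 · fat area / tissue area
```

by segmenting bright regions inside the tissue and then *excluding*
regions whose geometry says "vessel lumen, not vacuole". Who it is for:
groups running diet/treatment studies with histological endpoints who
need a reproducible, auditable number per slide instead of an eyeball
score.

## The algorithm

For each RGB photomicrograph:

1. **Luminance** — fixed 0.299 R + 0.587 G + 0.114 B weights; intensity,
   not colour, drives everything downstream.
2. **Tissue segmentation** — background is bright area (intensity > 0.92)
   connected to the image border; everything else, including enclosed
   vacuoles and vessel lumina, is tissue. The denominator is therefore
   whole parenchyma.
3. **Adaptive gray filter** — a per-slide brightness threshold adapts to
   staining variation: Otsu's threshold when the tissue intensity
   histogram is genuinely bimodal (stain vs. unstained fat), otherwise a
   bright-quantile fallback so a fat-free slide does not get split down
   the middle of its stain mode.
4. **Candidate regions** — 8-connected components of supra-threshold
   pixels inside tissue, with area, crack-edge perimeter, circularity
   (4π·area/perimeter²), solidity and border contact per region.
5. **Region filtering** — fixed precedence: area > 5,000 px →
   `excluded_large`; circularity < 0.4 or solidity < 0.85 →
   `excluded_shape`; touching the tissue border → `excluded_border`;
   regions < 30 px are dropped as noise; survivors are fat. Compact
   near-convex vacuoles pass; large, elongated or ragged lumina do not.

All thresholds live in a single `QuantConfig` (JSON-overridable, unknown
keys rejected). Defaults are sized for 512×512 images with vacuole radii
of roughly 4–16 px.

The package also implements the two oxidative-stress readouts of such
studies — MDA + 4-HDA by standard-curve inversion of 586 nm absorbances,
and protein carbonyls by Beer–Lambert (A = ε·l·c with ε = 22,000
M⁻¹cm⁻¹ for the DNPH derivative, reported as nmol/mg protein) — and the
statistics: percent change 100·(post − pre)/pre, Shapiro–Wilk-gated
paired t / Wilcoxon signed-rank comparisons per (group, variable),
Pearson/Spearman correlation, and pathologist-versus-program agreement
(mean difference and percent-change correlation).

## Worked example

```python
from steatoquant import (SlideSpec, generate_slide, quantify_slide,
                         CohortSpec, generate_cohort, run_group_analysis)

# a synthetic slide: 30% fat plus three vessel-like structures
slide = generate_slide(SlideSpec(target_fat_fraction=0.30, n_vessels=3,
                                 vessel_scale=130, seed=7))
result = quantify_slide(slide.image)
naive = quantify_slide(slide.image, apply_filters=False)
print(f"ground truth : {100 * slide.achieved_fat_fraction:.2f}%")
print(f"with filter  : {result.steatosis_pct:.2f}%")
print(f"naive        : {naive.steatosis_pct:.2f}%")

# a synthetic 4-group cohort, paired pre/post statistics
table = generate_cohort(CohortSpec(seed=1))
results, _ = run_group_analysis(table)
ast2 = next(r for r in results if r.group == 2 and r.variable == "AST")
print(f"group 2 AST  : {ast2.mean_pre:.1f} -> {ast2.mean_post:.1f} UI/L, "
      f"{ast2.test_used}, p = {ast2.p_value:.3f}")
```

prints

```
ground truth : 29.01%
with filter  : 29.01%
naive        : 38.59%
group 2 AST  : 72.2 -> 29.8 UI/L, paired_t, p = 0.002
```

The filtered estimate matches the generator's ground-truth mask to two
decimals, while the naive bright-area measurement overshoots by ~10
points — the vessel area it failed to exclude. The cohort line shows one
(group, variable) cell of the pre/post analysis: AST falls sharply in
the untreated-diet group, and since the paired differences pass the
normality gate the comparison used the paired t-test.

The same operations are scriptable from a shell:

```sh
steatoquant simulate slide --seed 7 --out slide/
steatoquant quantify --input slide/image.png --out results.csv
steatoquant simulate cohort --seed 1 --out cohort.csv
steatoquant analyze --cohort cohort.csv --out stats.csv
steatoquant assay carbonyl --plate plate.csv --out carbonyls.csv
```

Every run writes a `manifest.json` with the config snapshot, input
hashes, seeds and package version; identical seeds give byte-identical
outputs.

## Layout

```
src/steatoquant/
  image_io.py   slide/mask reading and writing (TIFF/PNG/JPEG)
  quantify.py   the quantification pipeline and its config
  synthetic.py  ground-truth slide and cohort generators
  assays.py     MDA standard-curve and carbonyl Beer-Lambert calculators
  stats.py      percent change, gated paired tests, correlation, agreement
  cli.py        the `steatoquant` command
docs/methods.md  model assumptions, parameter rationale, limitations
tests/           unit, property and end-to-end acceptance tests
```
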