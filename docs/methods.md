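# Methods

This note documents the models behind `her2ish`: what the synthetic slide
generator simulates, how the analysis pipeline works, which parameters
matter, and what the package's passing tests do and do not demonstrate about
real material.

## 1. Scoring rules

The quantification core is exact arithmetic and therefore the best-specified
part of the package.  A nucleus is *reportable* when it carries at least
`min_her2` HER2 and `min_cep17` CEP17 signals (defaults 2/2, selecting
nuclei with two complete chromosomes 17) and does not touch the ROI
boundary (truncated nuclei would bias counts down; the exclusion is this
package's choice).  Reporting takes the first `n ∈ [20, 200]` reportable
nuclei in a deterministic order — descending area, then ROI id and label —
since "the first n nuclei" is otherwise ill-defined for an automated reader.
Means are arithmetic; the ratio is the quotient of means (equivalently the
quotient of summed counts over the same nuclei).  The five ASCO/CAP ISH
group regions use inclusive boundaries at ratio 2.0 and 4.0/6.0 copies and
partition the non-negative quadrant (grid-checked in the tests).  Displayed
values are rounded to 2 decimals; classification always uses unrounded
values.

**Borderline definition.** "Borderline" is operationalised as ISH group
2–4 or a ratio in [1.8, 2.2] (the historical equivocal band around the 2.0
cutoff).  Borderline cases are re-counted at 40 nuclei, pooling further
ROIs if needed.  The 40-nucleus pass pools to 40 *total* (it does not
recount 40 fresh nuclei); the alternative reading exists but pooling is the
natural behaviour of an accretion loop.

**Monosomy reflex.** The inclusion minima are configurable
(monosomy preset 2/1, aneusomy 1/1).  `run_case` additionally applies an
automatic work-up: if ≥60% of detected non-edge nuclei carry fewer than two
CEP17 signals, the case is re-filtered under the monosomy preset.  Without
this, a chromosome-17 monosomy case is unreportable in principle: requiring
CEP17 ≥ 2 forces the reported CEP17 mean to ≥2, so a reported ratio ≥2
forces reported copies ≥4 and the group-2 region (ratio ≥2, copies <4)
becomes unreachable.  The 60% trigger corresponds to a true CEP17 mean
around 1.6 at the simulator's dispersions; ordinary disomic cases
(mean ≈ 2–3) stay well below it, and a spurious trigger is benign (the
relaxed filter moves reported means *closer* to the population means).

**Truncation inflation.** Conditioning on minimum counts inflates reported
means above population means, strongly for small means
(`E[X | X ≥ 2] ≈ 3.4` for a mean-2.6 count at dispersion 0.1).
`her2ish.profiles.truncated_count_mean` computes these expectations in
closed form; the group-targeted case sampler (§3) uses them so that the
*reported* statistics, not just the population ones, land inside the target
group region.

## 2. Synthetic slide model

Tiles are composed in optical-density (OD) space under Beer–Lambert mixing:
`RGB = I0 · 10^(−OD)`, `I0 = 245`, plus Gaussian sensor noise (σ = 1.5 grey
levels).  Components:

- **Nuclei**: soft-edged ellipses (axis ratio ≤ 1.25), mean radius 4.0 ±
  0.5 µm, hematoxylin amplitude ~N(0.72, 0.07) OD clipped to [0.50, 0.85].
  Placement is rejection sampling with pairwise lens-overlap ≤ 0.15 of the
  smaller nucleus; mild overlap is deliberate because overlapping nuclei are
  a known failure mode of automated readers.  Default density 3000/mm², a
  plausible invasive-carcinoma ROI.
- **Signals**: per-nucleus counts drawn from a negative binomial
  parameterised by mean and dispersion `a` (`Var = µ + aµ²`; `a = 0` is
  Poisson).  The container default is `a = 0.3`; profiles produced by the
  group-targeted sampler use `a = 0.1` (a fairly homogeneous tumour region —
  the variance that matters for group recovery at 20–40 nuclei).  Spots are
  placed uniformly within 0.75 of the nuclear radii, with a 0.7 µm minimum
  separation (closer deposits fuse optically and are uncountable by any
  reader), physical diameter drawn from 0.6–1.2 µm (prior centre 0.9 µm;
  the assay literature does not state a size; this spans ~3–8 px at the
  supported resolutions).  HER2 silver is rendered *achromatic* (equal OD in
  all channels, peak 1.3) because silver precipitate is grey/black rather
  than a dye; CEP17 uses a red-dominant Fast Red OD vector (peak 1.1).
- **Heterogeneity**: `amplified_fraction` draws that fraction of nuclei
  from a sub-population with 4× the HER2 mean while preserving the overall
  mean, so the closed-form expected ratio is unchanged.

All randomness flows from one integer seed through named child
`SeedSequence`s (`her2ish._rng`), making every image and sidecar
bit-reproducible and independent of sibling evaluation order.

## 3. Group-targeted case sampling

`sample_case_profile(group, seed)` draws means from per-group design boxes
chosen so that (a) closed-form expectations sit ≥0.2 from every group
boundary, and (b) the truncation-inflated reported expectations (§1) also
classify to the target group — under the monosomy preset for group 2, which
is monosomy-like by necessity.  Boxes (HER2/cell h, CEP17/cell c, ratio r):

| group | design box |
|-------|------------|
| 1 | r ∈ [3.4, 4.4], c ∈ [2.6, 3.2] |
| 2 | h ∈ [2.3, 2.5], c ∈ [0.55, 0.65] |
| 3 | h ∈ [7.2, 8.8], r ∈ [1.4, 1.7] |
| 4 | h ∈ [4.5, 5.0], r ∈ [1.3, 1.6] |
| 5 | h ∈ [2.2, 2.6], c ∈ [2.0, 2.4] |

Group-1 boxes sit well above ratio 2 because CEP17 truncation inflation
deflates the reported ratio by ~20–25% at these CEP17 means; a ratio-2.2
"group 1" case would be reported borderline or below.  The group-2 box is
the narrowest: the reported statistics must clear ratio 2 and stay under 4
copies *simultaneously*, and the total margin available between those two
constraints is `4 − 2·E[C | C ≥ 1]`, which only widens as the CEP17 mean
falls; the box therefore sits at severe monosomy, and its width accounts
for both the per-profile spread of the inflated expectations and the
counting noise of a 20-nucleus first pass (a case measured spuriously as a
clear group 1 never reaches the 40-nucleus extension).  The sampling noise of
a 20–40 nucleus count then still leaves a few percent of replicates on the
wrong side of a boundary — which is why the end-to-end recovery targets are
18/20 for the clear groups and 15/20 for the borderline ones, not 20/20.

## 4. Scanning-protocol degradation

`apply_protocol` maps a base render (fine resolution) to a protocol's view:

1. **Fade** — stain OD scaled by `fade_factor` (`t → t^fade` in
   transmittance), modelling pale scans.
2. **Resample** — anti-aliased downsampling to the protocol's µm/px;
   resolutions coarser than 2 µm/px are rejected (signals unresolvable).
3. **Blur and defocus** — Gaussian optical blur `blur_sigma_um`, plus a
   *patchy* focal-depth field: a smooth unit-variance random field
   soft-thresholded so most of the field is in focus and isolated patches
   drift out (how single-layer scans actually fail).  `focus_instability`
   raises both patch coverage and depth excursion (scale 4.5 µm at
   instability 1; 1 µm defocus ≙ 1 µm blur σ).  The field is keyed by the
   seed only — it belongs to the mounted slide and scan pass — so two
   protocols degrading the same base render see the same focal surface and
   paired comparisons isolate the protocol.
4. **Extended focus** — with `n_focus_layers > 1`, per-pixel defocus is the
   minimum over layer offsets (spacing `layer_step_um`), i.e. the sharpest
   layer is composited; residual defocus is capped at half the layer step.
   Spatially varying blur is approximated by interpolating between copies
   blurred on a fixed geometric σ ladder.

Shipped profiles: resolutions, numerical apertures and the 3-layer/1.4 µm
extended-focus geometry of A1/A2/B1/B2/B3/C1 are instrument facts
(scanner C's NA is unknown and recorded as `None`).  The blur/fade/
instability strengths are *qualitative calibrations* to each protocol's
described image character — A2 pale with clear signals, B1 focus-unstable
at its 40× resolution, C1 coarse, blurred and pale to the point of nucleus
detection failure — and are flagged `calibrated=False` where no stated
parameter backs them (C1).  An identity protocol (no degradation, same
resolution) returns the input bit-identically.

## 5. Analysis pipeline

- **Background**: per-channel I0 = 99th percentile of the tile (robust when
  no pure background is present), unless supplied.  OD uses ε = 1 grey
  level against log(0).
- **Stain separation**: least-squares projection of pixel OD onto two unit
  vectors — hematoxylin (0.65, 0.70, 0.29) from the classical published
  unmixing basis, Fast Red (0.09, 0.79, 0.60) modelled from its chemistry
  (red transmits red, absorbs green/blue).  Concentrations clip at 0;
  the residual map carries unexplained OD.  No third vector is used for
  silver: a grey precipitate has no stable chromatic direction.
- **HER2 channel**: mean OD weighted towards low colour saturation (silver
  is dark *and* achromatic), with red-chromogen pixels suppressed through a
  "redness" gate.
- **CEP17 channel**: the redness contrast `max((OD_G+OD_B)/2 − OD_R, 0)` —
  identically zero for achromatic silver, clipped to zero for hematoxylin,
  positive and *linear in fade* for red dyes.  A fixed saturation cutoff
  was rejected here: saturation collapses on faded scans and silently
  deletes CEP17 signals.
- **Nucleus segmentation**: smooth (σ = 0.25 r), Otsu threshold with
  adjustable offset and an absolute floor (0.12 OD), fill holes, watershed
  on the smoothed distance transform.  Seeds are distance-transform maxima
  *plus* nucleus-scale LoG maxima: a strongly overlapping pair's smaller
  partner has no distance maximum of its own, and LoG seeding recovers it.
  Regions pass explicit shape rules — area 20–300 µm², solidity ≥ 0.85,
  circularity ≥ 0.6 (Crofton perimeter, unbiased for digitised outlines) —
  plus a minimum mean hematoxylin concentration (0.18 OD), the mechanism by
  which pale scans lose nuclei.  Edge-touching regions are flagged and
  excluded from reporting.
- **Spot calling**: multi-scale scale-normalised LoG over σ spanning the
  physical diameter prior, greedy non-maximum suppression at one spot
  radius, ties broken by higher response then lower (y, x).  Response
  thresholds (HER2 0.15, CEP17 0.12 OD-response units) are the classical
  detector's operating point, calibrated on the generator's clean output.
- **Assignment**: a spot belongs to the nucleus whose mask contains its
  peak pixel; spots outside every mask stay unassigned and are never
  counted (no nearest-nucleus stealing of stromal specks).

## 6. ROI workflow and protocol evaluation

ROIs are simple polygons in slide micrometres (GeoJSON in/out); overlap is
rejected so nuclei cannot be counted twice.  ROI size is accounted as
uncompressed RGB megabytes (`W·H·3/10⁶`) — deterministic and
format-independent, deliberately not a viewer's on-disk compressed size; it
therefore scales with protocol resolution, and per-MB efficiency figures are
not comparable with viewer-reported ones.  Accretion processes ROIs in
annotation order and stops at the first ROI after which the reportable pool
reaches 20 (or 40 on the borderline pass); exhaustion below 20 yields an
"n/a" report.  Each ROI is analysed exactly once per case (cached), so
re-filtering and the borderline extension are free.

`compare_protocols` renders each case's ROIs once at a fine base resolution
and degrades them per protocol (paired design), then reports per-protocol
detected-nuclei counts and nuclei/MB over the *full* cloned ROI set (every
protocol sees the same tissue; counting only accretion-consumed ROIs would
penalise sharper protocols, which stop earlier), MB consumed at the
accretion stopping point, and concordance of the recovered group with
generator truth; differences are
tested with Kruskal–Wallis (chi-square approximation, the convention of
routine statistics software; an exact permutation mode exists and is checked
against enumeration in the tests) and all-pairs two-sided Mann–Whitney U
with Bonferroni adjustment (`min(1, m·raw)`).  All-identical data returns
H = 0, p = 1 by documented convention.  Box-plot whisker convention for any
downstream plotting of these tables: 1.5×IQR.

## 7. Problem sizes and determinism

The shipped tests run at desk scale: clean-detection checks use three
650² px tiles at 0.2 µm/px (≈40–60 nuclei each); group recovery uses
20 cases × 5 groups, each up to four 600² px ROIs; the protocol comparison
uses 10 paired cases × 4 protocols with 100 µm ROIs at a 0.12 µm/px base.
These sizes give the statistical resolution the acceptance properties need
(binomial bounds at 20 replicates; paired means over 10 cases) while keeping
the whole suite in the minutes range.  Every stochastic step takes an
explicit integer seed; identical (arguments, seed) give bit-identical
images, sidecars and reports.

## 8. What passing tests do and do not show

The generator produces idealised material: elliptical nuclei, near-uniform
counterstain, dot-shaped signals, no stromal clutter, no tissue folds, no
HER2 clusters (amplified signals in real tissue can coalesce into
uncountable aggregates), no section-truncation of nuclei, and degradations
that are smooth functions of five parameters.  Passing recovery tests
therefore demonstrate the *internal consistency* of the pipeline — counting
arithmetic, inclusion logic, accretion, classification, and the direction
of protocol-quality effects — not reader-grade performance on clinical
slides.  Real-slide concordance quantities are deliberately out of scope.
Known limitations: no learned segmentation (a classical stand-in replaces
the original CNN/SVM stages), no stain-vector auto-estimation, spot
detection assumes isolated dots, and the C1 degradation strengths are
qualitative.
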