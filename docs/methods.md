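# Methods

## Scope and design

`artix` converts a photograph of the dorsum of both hands into a
per-assessment finger-redness score and models the standardized
cold-challenge session around it. The pipeline stages are deliberately
decoupled behind small interfaces — segmentation, landmark provision, finger
extraction, colorimetry, session statistics — so any stage can be replaced
(e.g. a heavier neural segmenter, or landmarks from an external detector via
the landmark CSV) without touching the others. Landmarks are always consumed
through a provider abstraction; the package never calls an external landmark
framework directly.

Coordinates are 0-based with `x` = column, `y` = row and pixel-centre
sampling throughout.

## Segmentation

Two interchangeable paths produce the binary hand mask:

* **Classical** (default, deterministic): the background palette is the
  median colour of an 8-px frame border (the insulated matte surface the
  protocol prescribes); pixels whose RGB distance to it exceeds 60 are
  foreground. This is followed by morphological closing (disk radius 3) and
  retention of the ≤ 2 largest components (one or two hands per frame) —
  the cleanup prevents speckle from corrupting the colour statistics.
* **Trainable**: a seeded scikit-learn MLP (one hidden layer of 16 units)
  classifying each pixel from six features (raw RGB and σ = 2 px smoothed
  RGB), thresholded at probability 0.5 and cleaned up identically. A
  pixelwise classifier is entirely adequate for chroma-separable scenes and
  trains in seconds on a CPU; the `SegmenterModel` interface is the seam
  where an encoder–decoder could be swapped in for cluttered real-world
  backgrounds.

Mask overlap is reported as intersection-over-union. "Overlap" is sometimes
left unspecified in validation summaries; IoU is the stricter reading
(IoU ≤ Dice everywhere), so a ≥ 95 % IoU target also implies ≥ 95 % Dice.
The default working resolution is 512 × 512 after bilinear square-resize;
`resize_square` records per-axis scale factors (`side/W`, `side/H`) so
landmarks can be carried between grids.

## Finger extraction

The digit partition rule uses only the stated ingredients — landmarks plus
mask — and is deterministic. For digit *d* with skeleton polyline
MCP→PIP→DIP→TIP (MCP→IP→TIP for the thumb, whose CMC lies inside the palm),
a mask pixel joins *d* iff

1. its projection onto the proximal axis (MCP→PIP direction) is ≥ 0, i.e.
   distal to the MCP, and
2. its distance to the skeleton is ≤ *r_d* = 0.5 × (distance from *d*'s MCP
   to its nearest adjacent MCP), a scale-free half-width needing no
   calibration (the 0.5 factor is configurable).

Pixels eligible for several digits go to the nearest skeleton; exact ties go
to the lower finger index (thumb < index < middle < ring < pinky), which
makes the rule order-independent and mirror-symmetric. Digits are bounded
proximally at the MCP joint (not the interdigital web — the simpler of the
two defensible conventions). Thumbs are segmented and labelled but never
scored.

## Colorimetry and the redness formula

Within a finger region each channel is convolved with a Gaussian
(default σ = 2 px at 512 × 512) normalized over the region mask: the filter
weight of out-of-region pixels is zero, so borders do not bleed background
into the statistics, and a uniform region is exactly preserved. Quartiles
are linear-interpolation (type-7) quantiles of the smoothed values;
quartiles-on-smoothed (rather than raw) values is the chosen reading since
filtering precedes quantification. Regions under 25 px are rejected as
statistically unreliable; an assessment tolerates up to two lost scoring
digits (with a warning) before failing.

The per-finger redness is `median_R + (Q1_R + Q3_R)/2` — the median plus the
midhinge of the smoothed red channel. The exact published formula is not
recoverable; this instantiation was chosen because (a) it uses exactly the
stated ingredients (median and quartiles of the smoothed red channel) and
(b) for realistic skin red intensities (~150–205) it produces scores in
~300–410, matching the published dynamic range of the score. Green and blue
quartiles are always computed and reported; an optional penalty weight
(default 0) folds them into the score. All weights live in
`RednessWeights`, and the formula version string is carried in every output.
Absolute score equality with any published table is therefore not a meaningful
comparison surface; orderings, proportions and classification accuracy are.

ARTIX per assessment is the arithmetic mean of redness over all eight
non-thumb digits of both hands jointly (not per-hand-then-across-hands; the
two differ only when digit failures are asymmetric).

## Cold-challenge session model

The schedule is fixed: basal, then assessments at 0/2/4/6/8/10 minutes after
a one-minute 15 °C immersion — seven per subject. Thermography is
aggregated exactly as the reference protocol: mean temperature per digit
(II–V bilaterally), then the mean of the eight digit means — a mean of
means, which differs from the pooled-pixel mean unless all regions have
equal size (asserted in tests). "Returned to baseline" is
`value(10 min) ≥ value(basal)`, inclusive, so subjects who overshoot their
baseline count as returned.

## Synthetic generator

Hands are a filled palm ellipse plus five capsule-shaped digits with
per-digit angles, lengths and widths proportional to the palm radius —
simple, but with enough geometry (diverging digits, a thumb at a wide
angle, left/right mirroring) to exercise landmark-based extraction, and
with pixel-exact ground truth: mask, digit partition (thumb labelled
distinctly) and all 21 landmarks inside the mask by construction.
Defaulted geometry fields receive mild seed-derived jitter (palm radius and
centre, digit lengths and widths), so a set of seeds yields anatomically
distinct hands rather than one shape under different noise; explicitly set
fields are never jittered. Pixel
noise is i.i.d. Gaussian (default sd 8 intensity units) on both hand and
background; the background default is a dark near-black, emulating the
insulated surface.

Rewarming is mono-exponential toward a group-specific ceiling:

```
value(t) = basal · [c − (c − (1 − d)) · e^(−r·t)],   t ≥ 0 minutes
```

with drop fraction *d*, rate *r* and ceiling fraction *c*, plus i.i.d.
Gaussian measurement noise per assessment. No quantitative attack/rewarming
kinetics are published, so the population defaults are artifact choices
pinned to the reported qualitative structure and rough magnitudes:

| parameter | RP | HC | rationale |
|---|---|---|---|
| basal ARTIX mean (sd 22) | 341 | 394 | group contrast ≈ 30–40 units after covariate effects |
| ARTIX drop / rate / ceiling | 0.03 / 0.35 / 1.015 | 0.02 / 0.55 / 1.025 | redness dips little and overshoots by minute 10; HC rewarm faster and higher |
| basal temp °C (sd 2.2/2.6) | 27.9 | 30.8 | reference basal group means |
| thermal drop / rate / ceiling | 0.17 / 0.28 / 0.98 | 0.19 / 0.33 / 1.03 | temperature drops hard; RP stay below baseline at minute 10, most HC recover |
| season shift (Sep–Dec) | −25 units, −2 °C | same | colder-months offset, additive |
| covariate effects | male +12, vasoactive +14, ACA +20, late NVC −12, dcSSc −10 (units) | male +3 °C | direction and magnitude of the reported clinical associations |

Covariate prevalences follow a typical secondary-RP clinic cohort (91 %
female, 55 % on vasoactive therapy, 42 % ACA-positive, etc.; controls
healthy). `CohortConfig.expected_group_effect()` computes the analytic
HC−RP basal expectation implied by these marginals, which is what the
parameter-recovery test checks the analysis pipeline against (within 2 SE at
n = 45/22).

The generator emulates: chroma-separable hands on a dark background,
group- and season-dependent rewarming, paired thermal frames on the same
grid, and per-digit redness encoding (a digit's red channel is half its
redness value, since a uniform region scores 2 × R under the default
formula). It does **not** emulate photorealistic skin texture, skin-tone
diversity, shading/illumination gradients, camera colour response,
motion blur, or cluttered backgrounds — so passing tests demonstrate the
correctness and calibration of the *computational* pipeline, not
photographic robustness. Fast mode skips rendering entirely and emits
per-finger values, which is what the statistics-scale simulations use.

## Statistics

* **Routing**: Shapiro–Wilk on both samples at α = 0.05; both non-rejecting
  → two-tailed Student t; otherwise two-tailed Mann–Whitney U. The routing
  decision is recorded in the result.
* **2×2 chi-square**: Pearson, df = 1, *no* Yates continuity correction —
  the uncorrected statistic reproduces the reference contingency p-values
  (0.02 global, 0.03 Sep–Dec on the thermography return counts); the
  corrected one does not.
* **McNemar**: exact two-tailed binomial on discordant pairs (valid at small
  n; zero discordance returns p = 1 with a warning).
* **Regression**: OLS with an iterative VIF screen — auxiliary regressions
  include an intercept (so orthogonal predictors score exactly 1), perfect
  collinearity raises an error naming the offenders, and predictors are
  removed worst-first until all VIFs ≤ 10.
* **ROC**: empirical curve, trapezoid AUC, DeLong 95 % CI (midrank
  formulation), operating threshold by Youden's J. Lower ARTIX indicates
  RP, so the RP-positive orientation negates the score before ranking; the
  reported threshold is mapped back to the original scale.
* **Pooling**: "across all timepoints" comparisons are computed both ways —
  all assessments pooled and per-subject means — and labelled, since the
  convention is otherwise ambiguous.
* One-way ANOVA + Bonferroni and Kruskal–Wallis + Dunn wrappers are provided
  for >2-level covariates.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
512 × 512 resolution: 50 held-out hands for segmentation validation (the
trainable model fits on 100 in the acceptance script, 24 in the suite), 20
frames for the thumb-exclusion and digit-Dice checks, 2000 replicates for
the type-I-error calibration, and a 45 RP / 22 HC cohort for parameter
recovery — sizes chosen to make every property measurable with comfortable
statistical margin on a desktop CPU. Quantiles match a brute-force sort
oracle to 1e-9; chi-square matches its closed form to 1e-9; AUC matches the
Mann–Whitney identity U/(n₁n₂) to 1e-9. Degenerate inputs (empty masks,
off-mask landmarks, sub-25-px regions, single-class ROC, zero-margin
tables, zero discordance) raise typed errors or warn, as documented per
function.

## Known limitations

* The redness formula, the role of green/blue in the published score and
  the original unit scale are irrecoverable; only the formula's ingredients
  and output range are matched, and the formula is versioned in outputs.
* The synthetic hands are geometric, not photographic; segmentation numbers
  here say nothing about cluttered real scenes or diverse skin tones.
* Thermal frames are ingested as plain CSV matrices of °C; proprietary
  radiometric formats are out of scope (vendor software extracts them).
* The thermography ROIs reuse the photo-derived finger regions in synthetic
  sessions; real-world ROI polygons can be supplied through the landmark
  CSV mechanism instead.
* Clinical covariate effects are additive and independent in the generator —
  adequate for testing the regression machinery, not a disease model.
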