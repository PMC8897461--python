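# Methods

`csdstools` re-implements, as a tested library, the quantitative workflow of
a chronic-social-defeat-stress (CSDS) mouse study: behavioral phenotyping by
symptom load, motor-learning curve analysis, longitudinal dendritic-spine
turnover, microglia morphometry with dendrite colocalization, and CSF
proteomics regulation calling.  Because such studies rarely deposit raw
per-animal data, the package ships a synthetic-cohort generator with
recorded ground truth; every estimator is validated by parameter recovery
on that generator.

## Behavioral phenotyping

Three tests are scored per animal after the 10-day defeat period: sucrose
preference (%, anhedonia), nestlet shredding (score 0–5, self-care) and
social interaction time (s, avoidance).  Sucrose preference is computed from
bottle masses over two 24 h periods (bottles switched at 24 h):
`100·Δm_sucrose/(Δm_sucrose + Δm_water)` per period, averaged.  A bottle
gaining mass or a period with zero total consumption is a measurement error,
never silently patched.

A test is *pathological* when its value lies below its cutoff: 60 %,
score 4, 50 s.  All three cutoffs are applied strictly-below; the
interaction cutoff's convention is not fixed in the field, so an inclusive
variant is a flag (`CutoffSet.interaction_inclusive`, default off).  The
*symptom load* is the number of pathological tests; stressed animals with
load ≥ 2 are **susceptible**, the rest **resilient**; control animals with
load ≥ 2 are excluded from analysis.  Missing test values raise — the load
rule presumes three results, and imputation would silently shift the
classification boundary.

Defeat sessions are summarized per animal as attack count and mean severity;
severities live on a 1–3 grid in 0.5 steps and off-grid values are rejected.

## Motor learning

Rotarod learning curves (15 trials, capped at 90 s) are fitted with a
four-parameter Hill sigmoid over the trial index x = 1..15:

    t(x) = t0 + (tmax − t0) · x^h / (ls50^h + x^h)

A free baseline `t0` is kept because first-trial times are nonzero and a
zero-baseline form would bias the midpoint.  Bounds: `t0, tmax ∈ [0, 90]` s,
`ls50 ∈ [0.5, 30]` trials, `h ∈ (0, 10]`.  The least-squares problem is
solved from a deterministic multi-start grid (`h ∈ {0.5, 1, 2, 4}`,
`ls50 ∈ {2, 5, 8, 12}`, fixed order; `t0`/`tmax` start at the series
min/max) and the lowest residual sum of squares wins, which makes the fit
reproducible and robust to the local minima a single start hits on noisy
series.  Capped trials enter the fit as-is (no censoring likelihood); a
fitted `tmax` within 0.5 s of the cap is flagged at-bound.  An all-constant
series is a flagged flat fit with undefined `ls50`/`h`.

Learning speed is reported twice: the fitted `ls50` parameter, and the
literal reading — the smallest x with t(x) ≥ 0.5·tmax, solved in closed
form on the fitted curve.  The two coincide when t0 = 0; which one is "the"
LS50 is left to the caller since the original description is ambiguous.
When t0 already exceeds half-maximum the literal value is 0 with a flag.

Skilled-reaching success is simply `100·successes/48` per day (success =
pellet eaten after the first or second correct reach); a day without exactly
48 outcomes is invalid.

## Spine turnover

Input is a long-format presence table: one row per (ROI, spine, session)
with state `present`/`absent`/`not_imaged`, the spine's length at first
detection and the ROI's constant dendrite length.  Protrusions shorter than
0.4 µm (exclusive) are not spines.  The imaging schedule is day −10
(baseline) and days 2, 5, 11, 17 after the last defeat, optionally extended
to 23/29/35; consecutive intervals must stay within the 3–12-day window the
re-identification protocol tolerates.

Rules and conventions:

- **ROI inclusion** — only ROIs imaged at baseline *and* day 2 are analyzed;
  later gaps are retained as missing, never interpolated.
- **Density** — count/dendrite-length (µm⁻¹); normalized density is
  100·count/baseline count, so baseline ≡ 100 %. Zero-baseline ROIs are
  flagged, not divided.
- **Turnover** — per interval, gained = present now but not before, lost =
  present before but absent now; fractions are normalized by the
  previous-session count (interval-specific turnover, the standard in the
  longitudinal spine literature; a baseline-count denominator is a config
  option since the original wording does not fix one).  GLR =
  gain/loss fraction; > 1 is net gain.  When nothing was lost the GLR is
  reported as missing with a flag, never infinity.  Count conservation
  N_t = N_{t−1} + gained − lost is asserted on every interval.
- **Re-emergence** — a spine absent and later present again must carry a new
  id; positional identity across a gap is not defensible from session
  snapshots.  This makes survival fractions monotone by construction, and a
  violation raises.
- **Survival** — the cohort for a motor task is every spine first present at
  the session right after it (rotarod → day 5, reaching → day 11), assessed
  at all later sessions.
- **Aggregation** — group mean ± SEM at ROI level by default, animal level
  as an option, with both n's reported; the original figures are ambiguous
  between the two units.

Relative density changes between groups are reported as percentage-point
differences of normalized densities (the convention behind statements like
"−22 % versus control levels"); a ratio-based alternative is emitted
alongside.

## Glia morphometry and colocalization

**Triangle threshold.**  Given an intensity histogram, the chord runs from
the peak bin to the farthest nonzero bin on the longer-tail side; the
threshold is the bin between them maximizing the perpendicular distance to
the chord, ties broken toward the tail.  Flat or single-bin histograms have
no triangle geometry and raise.  Thresholding operates on the full image
histogram per channel, matching the Fiji-style workflow it emulates.

**Cell metrics** (per pre-separated, single-component mask):

- total area = pixel count × pixel area;
- spanned area = convex hull of the pixel squares (corners at centers
  ± 0.5 px), which guarantees total ≤ spanned;
- tree length = skeleton (topological thinning) path length with 1-px
  orthogonal and √2-px diagonal steps; a diagonal is skipped when both
  flanking orthogonal links exist, so corners are not double-counted;
- ramification index = perimeter / (2·√(π·area_px)) — the perimeter of the
  shape relative to that of the equal-area circle, 1.0 for a disc.

The perimeter uses the Crofton 4-direction estimator.  Weighted
boundary-crack counting is also available (`perimeter_method="crack"`), but
it overestimates a rasterized disc's perimeter by ~5 %, which would push the
disc's ramification index to ~1.05; Crofton keeps it within ~0.5 % at the
radii used here.

**Colocalization.**  Within a dendrite-segment ROI of at least 30 µm,
yellow = above threshold in both channels, green-only = dendrite channel
only; the reported ratio is yellow/(yellow + green-only), pooled over the
ROI.  No green pixels → undefined, flagged.  Area coverage is
|mask ∧ region|/|region|.

## Proteomics regulation calling

The workflow mirrors a Perseus-style analysis of a protein-group × sample
intensity matrix over three groups (control/resilient/susceptible, design
17/11/10):

1. valid-value filter: keep proteins with ≥ 2 observed values in *every*
   group (the stricter of the two readings of "fewer than two observations
   in each group"; the laxer any-group reading is a config option);
   contaminant removal by explicit id list or flag column — no hard-coded
   species logic.  Both filter orders are supported and counts are logged at
   each step, since published pipelines differ here.
2. log2 transform and per-sample median subtraction (observed median exactly
   0 afterwards; missing values propagate);
3. per-comparison differences of group means (replicates averaged first);
4. **Significance A**: with m the median of the differences and the
   asymmetric spreads σ_right = P84.13 − m, σ_left = m − P15.87 (one-sigma
   Gaussian quantiles, linear-interpolation percentiles — the σ estimates
   depend on this convention, so it is fixed and documented), the z-score is
   (d − m)/σ_right above the median and (m − d)/σ_left below; two-sided
   p = min(1, erfc(z/√2)).  Checkpoints: p = 1 at the median, p ≈ 0.3173 at
   the 84.13th percentile; under a pure Gaussian the p-values are uniform.
5. Benjamini–Hochberg adjustment within each comparison (delegated to
   statsmodels; a hand-rolled step-up rule serves as the independent test
   oracle);
6. regulated ⇔ q < 0.05 and |Δlog2| ≥ 1 (two-fold, boundary inclusive),
   direction by sign.

An optional one-sided hypergeometric over-representation test against
user-supplied term→id tables (BH across terms) stands in for external
pathway databases; no network access is involved.

## Synthetic cohorts

The generator produces each modality at the reference study conditions:
23 control and 26 stressed mice with a susceptible fraction of 14/26;
imaging days (−10, 2, 5, 11, 17); proteome of 1906 protein groups over
17/11/10 samples; 1024-px images at 0.44 µm/px (a 450 µm field).  One seed
fans out to independent per-stage streams (`(seed, stage_tag)`), so adding a
stage never changes another stage's data, and identical (config, seed) is
bit-identical.

Choices where the emulated study prints no distribution (all module
defaults, labeled as such):

- **Behavior** — healthy test values are Gaussian around (75 %, 4.6, 80 s)
  with sd (8, 0.6, 15), truncated to physical ranges after noise; the
  susceptible component is centered `effect` beyond each cutoff (default
  15 pct-points, 1.5 score, 30 s — clear but overlapping separation, as in
  real cohorts).
- **Rotarod** — per-phenotype Hill parameters (control 20→60 s, ls50 6;
  resilient 20→75 s, ls50 4.5; susceptible 18→35 s, ls50 5; 5 s trial
  noise) mirroring the reported pattern: resilient above, susceptible far
  below control, equal first-trial times.
- **Spines** — discrete per-interval Bernoulli death / Poisson birth (only
  session snapshots are observed, so a continuous-time model would add
  unidentifiable structure).  Per-interval loss/gain of 0.10/0.15 (control),
  0.19/0.10 (resilient), 0.27/0.10 (susceptible) put the expected day-2
  normalized densities near 105/91/83 %.  Task-born spines get a separate
  next-interval survival probability.
- **Microglia** — stick-figure cells: 3–6 branches per cell radiating at
  jittered, evenly spaced angles (so processes do not run on top of each
  other, as in ramified cells), lengths 50–110 px, dilated to a 2-px
  half-width, on background 12 ± 4 vs foreground 140 grey levels.  Ground
  truth stores the analytic polyline step length, the analytic convex hull
  of the buffered polylines, and the exact rasterized pixel count.
- **Coloc** — per segment, exactly `round(fraction·n_pixels)` dendrite
  pixels are also set in the red channel, so the measured ratio equals the
  planted one deterministically; red-only clutter avoids green pixels.
- **Proteome** — per-protein base level N(20, 2) in log2, per-sample loading
  offset N(0, 0.2) (removed by median centering), measurement noise
  N(0, 0.3), values missing completely at random at rate 0.1
  (intensity-dependent missingness is deliberately not modeled — the
  emulated workflow does not model it either and it would entangle the
  filter and the spread estimate); 15 proteins spiked ±2 log2 units in the
  susceptible group and 15 in the resilient group.

What the generator does **not** emulate: correlated test batteries within
animal, session-to-session registration error and detection noise in spine
scoring, 3-D morphology and partial-volume effects in imaging,
intensity-dependent missingness and shared-peptide effects in proteomics.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to every artifact of real
data.

## Problem sizes and tolerances in the test suite

Recovery checks run at sizes where the Monte-Carlo error is far below the
assertion band: classifier recovery on 20 cohorts × 200 stressed animals
(≥ 95 % agreement at 5-sd effects); LS50 recovery on 200 noisy curves
(median error < 1 trial); day-2 density on 10⁴ spines at loss 0.17 (83 %
± 1.5 points, 4 binomial sigmas); task-born survival on ~10⁴ spines (0.75
± 0.02); triangle threshold against a brute-force oracle on 1000 random
histograms; Significance-A calibration on 10⁵ Gaussian deltas (fraction
below 0.05 within ± 0.005).  Geometry recovery tolerances (5 %) cover
rasterization: skeleton tips retract by about the dilation half-width and
hulls differ by sub-pixel boundary placement.

## Known limitations

- The Hill fit treats capped trials as exact observations; heavy capping
  biases `tmax` toward the cap (flagged, not corrected).
- The ramification index is a 2-D perimeter-based convention; MotiQ-style
  plugins may define it differently, so absolute values are comparable only
  within this package.
- Significance A is computed on group-mean differences; variants computed on
  individual sample ratios will differ, particularly at small group sizes.
- The behavioral classifier keeps the first classification fixed; re-tests
  are reported separately and never overrule the label.
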