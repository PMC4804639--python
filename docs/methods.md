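# Methods

This note documents the models and conventions behind `gazeclass`: what the
synthetic cohort emulates and what it does not, how the latent attention
model is calibrated, the statistical conventions of each analysis stage, and
the design decisions taken where the published description leaves the
procedure open.

## 1. The battery and the fixation metric

The battery is eight movies on a 1280 × 1024 monitor sampled at 50 Hz:
five face clips A–E (7, 7, 4, 3, 7 s), biological motion F (20 s), and two
people-vs-geometry clips G (16 s) and H (16 s).  A–E carry eyes/mouth AoIs,
F upright/inverted, G people/geometry, H a single geometry window.  The
primary ("AoI-1") region is the socially salient one except in H, where it
is the geometric window.  Attention-reorienting animations between stimuli
contribute no samples to any stimulus.

AoI pixel rectangles are **documented placeholders** (the device's geometry
is proprietary): an eye band and mouth band over the central face, left and
right panels for the side-by-side clips, a lower-right window for H.
Rectangles are half-open `[x0,x1)×[y0,y1)`, origin top-left, so boundary
samples are never double-counted and a point on the right/bottom edge is
outside.  Geometry affects only where simulated samples land and how they
are recounted; every statistic consumes the derived percentages, which are
calibrated directly (§3), so the placeholder geometry does not influence the
analysis results.

Percentage fixation is raw-sample dwell over the **full scheduled duration**
(invalid samples count in the denominator).  There is no fixation-event
detection (no I-VT/I-DT velocity filtering), no blink interpolation and no
smoothing: the instrument reports raw-sample ratios, and this choice is what
makes the published per-stimulus rows sum to less than 100%.  Availability
is the valid share of all scheduled samples across the battery; exclusion is
strict (`availability < 80`), with the threshold configurable.

## 2. What the synthetic cohort emulates

The generator reproduces the case-control structure of the study:

- **group sizes** 26 ASD / 35 TD, with exactly five ASD participants drawn
  as "low-tracking" cases at availabilities 60, 58, 53, 52, 31 % (the count
  is the rounded group probability 5/26 × n, so scaled-up cohorts keep the
  same mixture proportion);
- **per-AoI fixation percentages** whose group means and SDs match the
  published per-item summaries (§3);
- **psychometrics**: SRS totals drawn from N(111.8, 18.5²) for ASD and
  N(53.6, 16.9²) for TD, rounded and clamped to [0, 195], with four ASD
  SRS values missing; FSIQ N(99.8, 13.5²) in the ASD group only.  The
  missing-SRS participants are drawn among the *normally tracking* ASD
  cases so that the included group reproduces the published n = 17 with
  usable SRS.  SRS is independent of gaze by default — the study found
  almost no within-group correlation — with an optional coupling knob
  (`srs_fixation_r`) for power experiments;
- **sampling**: per stimulus, every scheduled sample is independently
  invalid with probability 1 − availability/100, otherwise placed uniformly
  in the AoI or out-of-AoI region chosen by the participant's attention
  profile.

Deliberately **not** modelled: saccade/dwell dynamics (the analysis consumes
only time-aggregated percentages, so per-sample independence is sufficient
and avoids unconstrained parameters), calibration error, head pose,
covariance of attention across stimuli (each stimulus's profile is an
independent draw), and any AoI covariance within a stimulus beyond what the
sum constraint induces.  Consequently, passing tests validate the pipeline's
arithmetic and the marginal group structure, not temporal gaze dynamics or
cross-stimulus dependence in real recordings.

A distributional shortcut (`simulate_fixation_table`) draws the per-category
sample counts directly from the same multinomial law instead of
materialising streams; large-cohort checks use it, and a test confirms the
two paths agree.

## 3. The latent attention model and its calibration

Per participant and stimulus, the latent profile is: one normal draw per
AoI, clipped to [0, 100], then rescaled proportionally whenever the
within-stimulus sum exceeds the participant's availability *a* (a
participant cannot allocate more measured time than the tracker records).
Valid samples are assigned to AoI *j* with probability *p<sub>j</sub>/a*, so
the expected measured percentage equals the latent profile value.

Two calibration problems arise, both solved inside the package
(`gazeclass.calibration`), with the fitted latents shipped as package data
(`data/latent_calibration.csv`, regenerable via
`gazeclass.cohort.regenerate_latent_table`):

**Availability.**  The published availability of included participants
(ASD 95.3 ± 5.5, TD 97.2 ± 3.1) must be reproduced *after* conditioning on
inclusion.  No truncated normal on [80, 100] has these moments (the family's
SD tops out near the uniform 5.77 only around mean 90), and naively
truncating N(95.3, 5.5²) drops the mean to 93.5.  Normal-tracking
availability is therefore a scaled Beta on [82, 100], moment-matched in
closed form.  The 2-point margin above the threshold also makes the
exclusion count deterministic: per-sample binomial noise on realised
availability (SD ≈ 0.6 points at 4000 samples) cannot push a nominally
included participant below 80%.

**Attention latents.**  Clipping and rescaling shift moments, so setting the
latents to the published means/SDs biases every derived mean down by 3–6
points.  Latents are instead fitted jointly per (group, stimulus) —
Nelder–Mead on a fixed common-random-numbers sample (N = 120 000, internal
seed 12345), minimising squared errors of the post-process means (weight 4)
and SDs (weight 1).  For stimuli whose published AoI means sum to nearly the
whole available recording (F and G), rescaling is active for most draws and
the objective becomes invariant to scaling all latents up together; a soft
penalty on latent locations beyond ±250 breaks this ridge and selects the
least-saturated, least shape-distorting solution.

Calibration quality, measured on fresh draws at n = 2000 per group: every
derived group mean within 1.5 percentage points of its published target
(most within 0.3) and every SD within 7% relative.  Two structural limits
are worth recording:

- **Biological motion, ASD**: the published upright + inverted means sum to
  97.4% while the published included-ASD availability mean is 95.3%, and
  measured percentages cannot exceed availability under a single
  per-participant availability.  The residual is split proportionally
  (≈ −1.0 to −1.3 points per AoI) — inside the 1.5-point band, but it is a
  cap, not noise.  (The real device plausibly had higher per-stimulus
  validity during F than the battery-wide average; a per-stimulus
  availability model would add a parameter the published tables cannot
  constrain.)
- **People-and-geometry AUC**: in the saturated regime the *shape* of the
  derived distribution is not identifiable from means and SDs alone.  Every
  moment-matched solution of this latent family implies a population AUC of
  ≈ 0.79 for the people region, against the published in-sample 0.74 (95% CI
  .60–.88).  The generator is statistically compatible with the published
  estimate, but reproduction of that AUC to ±0.05 at large n is knife-edge
  and the corresponding check is allowed to fail rather than re-tuning the
  generator toward it; the blinking-eyes and silent-eyes AUCs (0.80, 0.75)
  reproduce comfortably.

## 4. Statistical conventions

- **t variant**: per item, a center-mean Levene test at α = .05 chooses
  pooled vs Welch (the common statistics-package behaviour); explicit
  `pooled`/`welch` policies are selectable.  The published rows are a mix —
  still-image eyes matches pooled (2.82 vs printed 2.83), blinking eyes
  matches Welch (3.83) — and in the summary-level reanalysis, where raw
  values do not exist, the variant closest to the printed t is used and
  recorded.  Recomputation from the printed (rounded) summaries matches
  every printed t within 0.1 and every printed d within 0.03.
- **Cohen's d** always uses the df-weighted pooled SD, reported as an
  absolute value, regardless of the t variant (all printed d values match
  the pooled form).  Flags: medium d > 0.5, large d > 0.8, both strict.
- **Bonferroni**: α = .05 / #AoIs per stimulus (.025 two-AoI, .05 for H).
  The preliminary availability comparison sits outside every family at .05.
- **Correlations**: product-moment r, within group, uncorrected .05, missing
  covariates dropped pairwise (SRS in both groups; FSIQ in ASD only).  No
  multiplicity control, matching the published single-star convention.
- **AUC**: midrank-based (ties count ½), oriented so the ASD-typical
  direction scores positive; confidence intervals by the Hanley–McNeil
  normal approximation (the published CI method is unstated; these
  intervals are reported, not asserted against).
- **Cutoffs**: the publication does not state how cutoffs were derived from
  the ROC; Youden's J over midpoints between adjacent distinct pooled values
  (plus one candidate beyond each extreme) is adopted, ties broken toward
  higher specificity, then toward classifying fewer participants as
  ASD-like.  Printed integer cutoffs are treated as report-level rounding
  and are also shipped verbatim so the published classifier can be applied
  independently of re-derived cutoffs.
- **Count-threshold semantics**: the published rows labelled "> N items"
  are implemented as **"at least N items met"** — the only reading under
  which the published combination counts reproduce every printed row (e.g.
  20/21 = 95.2% sensitivity at N = 1).  The prose "more than two items" is
  loose wording.  This is the single most consequential interpretation in
  the package.
- **PLR/NLR reporting**: exact fractions are kept on the result objects;
  the *reported* one-decimal values are recomputed from the one-decimal-
  rounded percentages, halves away from zero — the convention under which
  every printed row reproduces exactly (81.0/20.0 = 4.05 → 4.1, where the
  exact fraction gives 4.048 → 4.0).  Specificity 1 yields an infinite-PLR
  sentinel with a warning, never an error.

## 5. Scope and known limitations

- The discriminant analysis is **in-sample**: cutoffs, panel and thresholds
  are selected and evaluated on the same cohort, so the reported
  sensitivity/specificity are optimistic relative to out-of-sample use.  No
  cross-validation is attempted, mirroring the original analysis; the tool
  is a supplementary screen, not a diagnostic.
- The published all-eight-item analysis (sensitivity 61.9%, specificity
  85.7% at "more than four items") is implemented by the same sweep
  (`panel="all_aoi1"`), but its printed numbers cannot be reconstructed from
  published data — no per-participant eight-item breakdown exists in print —
  so they are not asserted anywhere.
- Whether the device computes availability over calibration and
  attention-getter segments is unstated; scope here is the eight stimuli.
- Test and acceptance problem sizes: the full-stream default cohort (61
  participants, 244 000 samples) exercises the sample-level path; the
  distributional shortcut runs the 2000-per-group consistency checks.
  These sizes keep the whole suite well under a minute while leaving Monte
  Carlo error well below the asserted tolerances.
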