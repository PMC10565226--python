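# Methods

`snakegaze` re-implements, as a tested pipeline, the gaze-processing and
statistical analysis of a paired-stimulus ("preferential looking")
eye-tracking design: on every slide, two photographs of the same snake
specimen — one in a threatening posture, one relaxed — compete for a
participant's spontaneous attention for 5 s.  The question is whether, and for
which snake morphotypes (cobras, vipers, others), gaze is biased toward the
threat display, and whether Somali and Czech participants differ.  Because
the raw study recordings are not redistributable, the package includes a
synthetic gaze generator so that every stage is exercisable, and its tests
meaningful, without them.

## Study design objects

- **Stimulus catalogue.** 20 species — 8 cobra-morphotype elapids, 8 vipers,
  2 pythons and 2 colubrids (pythons and colubrids form the "other"
  morphotype) — each in two horizontally mirrored slide versions (threat on
  the left / right), plus one practise slide that never enters analysis.
- **Presentation orders.** Four orders: order 1 is a seeded semi-random
  sequence in which half the species (4 cobras, 4 vipers, 1 python,
  1 colubrid, both versions of each) precede the rest; order 2 is order 1
  reversed; orders 3 and 4 mirror every slide of orders 1 and 2.
  "Semi-random" is implemented as a uniform shuffle within each 20-slide half
  under the composition constraint, fixed by the seed.
- **AOIs.** The screen (1366 x 768 px, viewed from ~60 cm) carries three
  disjoint interest areas: full-height lateral rectangles of width
  `round(0.37 * width)` at each edge (36.97% of the screen each) and a
  central square of 1% of the screen area centred on the fixation-cross
  location.  Only the area fractions are constrained by the design; the
  rectangle shapes are this package's choice and do not affect side-level
  metrics for laterally placed stimuli.  Coordinates are screen pixels,
  origin top-left, x rightward, y downward.  Rectangles are half-open
  (`[x0, x1)`), and the horizontal mirror of a continuous gaze coordinate is
  `width - x`, under which the lateral AOIs swap exactly.

## Gaze processing

- **Binocular averaging.** Both eyes valid: midpoint.  One eye valid: that
  eye's coordinates (a strict both-eyes mode is available).  Neither: the
  sample stays in the timeline as invalid.
- **Fixation detection** is a lead-sample dispersion rule: the first valid
  sample is the lead of a prospective fixation; each subsequent valid sample
  within 23 px (0.5 deg) of the lead joins it; the first sample beyond that
  radius closes the group and becomes the new lead.  A group is a fixation
  when it has at least 2 members.  Grouping is strictly sequential (a sample
  that would fit an earlier lead after an excursion does not rejoin), and a
  run of invalid samples closes the current group — fixation membership
  requires temporal contiguity, so a blink ends a fixation.  Duration is
  `(last - first member time) + one sample interval`, making an n-sample
  fixation at rate r last exactly n/r; a full 150-sample trial at 30 Hz is a
  5000 ms fixation.  A fixation's AOI is the AOI of its centroid (robust to
  a lead sitting on a boundary).
- **Dwell time** is sample-based: valid samples whose position lies in the
  AOI times the sample interval (computed as `count * 1000 / rate` so that
  60 samples at 30 Hz give exactly 2000 ms).  It is deliberately *not* the
  sum of fixation durations: singleton leads still represent gaze on the
  stimulus, and the quality cut below operates on raw gaze time.

## Curation

Practise trials are dropped.  A trial is excluded when its combined dwell on
the two lateral AOIs is strictly under 2000 ms (exactly 2000 ms is kept; the
threshold is configurable).  Surviving trials are averaged over the two
mirror versions of each species — threat-side metrics are read off each trial
according to its threat side first — giving one observation per participant x
species with observation weight 2 (full pair) or 1 (lone survivor).  Averaged
fixation counts may be half-integer and are kept as such.  Averaging the four
raw metrics and then differencing equals averaging the differences.  The
response variables are `diff_fix = fix_threat - fix_relax` and
`diff_dwell_ms`; positive values mean more attention to the threat display.
The demographic age comparison is a Mann-Whitney U with tie-corrected normal
approximation (no continuity correction), with an exact permutation option
for small samples.

## The mixed model

For observation i of participant p(i):

    y_i = x_i' beta + b_p(i) + e_i
    b_p ~ N(0, sigma_b^2)
    e_i ~ N(0, sigma^2 * exp(2 delta g_i) / w_i)

`g_i` flags the non-reference nationality (reference = first level
alphabetically, i.e. Czech) and `w_i` is the observation weight — the
"constant variance by nationality x fixed variance by weight" residual
structure.  The full fixed structure is intercept + morphotype + nationality
+ gender + age + morphotype:nationality + gender:nationality, treatment-coded
with alphabetically first reference levels.

The (restricted) likelihood is evaluated exactly per participant block via
the rank-one structure of each block's covariance (Sherman-Morrison), with
beta and sigma^2 profiled out; the optimiser runs L-BFGS-B from a fixed
multi-start grid over `(gamma, delta)` with `lambda = gamma^2 =
sigma_b^2/sigma^2` (gamma in [0, 1e4], delta in [-5, 5]), followed by a
Nelder-Mead polish (function tolerance 1e-13).  Fits are therefore
deterministic, and `sigma_b^2 = 0` is a reportable boundary, not an error.
On a shared fixture the engine reproduces nlme's `lme(..., weights =
varComb(varIdent(~1|nationality), varFixed(~1/w)))` log-likelihood, AIC,
variance components and coefficients to print precision (session
cross-check; the shipped tests use a dense multivariate-normal oracle and
closed-form balanced-design REML instead).

- **Model reduction.** Backward elimination at alpha = 0.05 on REML fits:
  every eliminable term (interactions before their main effects; a main
  effect only when no retained interaction contains it) gets a marginal Wald
  F-test; the worst term with p >= alpha is dropped and the model refit.
  The full and final structures are then refit by ML for the
  likelihood-ratio test (2 delta-logLik vs chi-square on the dropped
  parameter count) and AIC (`-2 logLik + 2 (p_fixed + p_variance)`,
  variance parameters = sigma_b^2, sigma^2 and delta when active).
- **Denominator df** follow a two-level inner-outer rule: terms constant
  within participants (nationality, gender, age, gender:nationality) are
  tested against `M - p_between` df, where M is the participant count and
  p_between the non-intercept parameters at that level; terms varying within
  participants (morphotype and its interactions) against
  `n - M - p_within`.  With 142 participants and 2737 curated observations
  this yields the dfs the study design implies (138 and 141 between; 2591
  and 2593 within).  Satterthwaite/Kenward-Roger approximations are out of
  scope.
- **Marginal means** average the treatment-coded design row equally over the
  levels of non-focal factors, with covariates (age) at their sample mean.
  Cell means are tested against zero on within-participant df; nationality
  contrasts use between-participant df, matching the level at which the
  factor varies.

## The synthetic generator

The generator's defaults are the study's conditions: 142 participants
(71 Somali, 71 Czech; 25 women and 46 men each), ages from truncated normals
(Somali mean 22.37, range 19-39; Czech mean 24.63, range 18-44), uniform
random order assignment, 41 slides (practise first) of 5 s at exactly 30 Hz
(the regular timebase is a determinism choice), and the AOI geometry above.

A trial is a sequence of fixation episodes (duration ~ clipped normal, mean
230 ms, sd 80 ms, minimum 2 samples) separated by 1-sample saccade transits.
An episode lands on the central AOI with probability 0.08 (gaze returning to
the fixation-cross region) and otherwise picks the threat side with
probability `logistic(bias + participant offset + trial disturbance)`:

- `bias` per nationality x morphotype; the defaults were calibrated by
  brute-force simulation of this generative model so the expected
  fixation-count differences are ~1.85 (cobras), ~0.46 (vipers) and ~0.28
  (others), split across nationalities in proportion to the design's
  dwell-difference pattern (the measured slope is ~9.1 fixations of
  difference per unit log-odds);
- participant offsets ~ N(0, 0.15) persist across a participant's trials and
  are what the random intercept recovers;
- trial disturbances ~ N(0, 0.20) for Czech and N(0, 0.24) for Somali
  participants exercise the nationality variance structure.

Within an episode, samples jitter around the anchor with sd 5 px (well under
the 23 px dispersion radius, so one episode is one detected fixation); each
eye reports the common gaze point plus independent N(0, 2 px) noise, and each
eye sample is independently invalid with probability 0.02.  With probability
0.0734 per trial — the study's exclusion rate — a contiguous block of at
least two-thirds of the trial is invalidated (tracking loss/distraction),
which guarantees the trial fails the 2000 ms cut; the single dropout process
stands in for whatever mixture of distraction and tracking loss produced the
study's exclusions.  Episode statistics put ~18 fixations and ~4.4 s of
lateral dwell in a typical trial, matching the study's per-trial means.

What the generator does **not** emulate: saccade dynamics and smooth pursuit,
calibration drift, pupilometry, species-level (as opposed to
morphotype-level) attentional structure, and any dependence of the two
responses beyond the shared side-choice process.  That last point is a real
limitation: one Bernoulli side choice per episode drives fixation counts and
dwell times jointly, so the generator cannot match the study's fixation
differences and its larger dwell differences (e.g. 584.7 ms for Somali
cobras) simultaneously; defaults favour the fixation-count targets, leaving
simulated dwell differences ~15% below the corresponding published ones.
Passing tests therefore show that the pipeline recovers what this generator
injects under the study's dimensions — not that the generator reproduces
every moment of the real data.

## Problem sizes used by the shipped checks

`scripts/acceptance.py` runs one full-scale study (142 participants, 5680
experimental trials, ~873k gaze samples, ~20 s).  The parameter-recovery
test uses 100 replicate studies per condition at a reduced size chosen for
statistical adequacy per replicate (24 participants, 6 species) with the
injected truth estimated by direct brute-force simulation of the generative
model; oracle-equivalence checks use 500 random streams and 25 random
mixed-model datasets of up to 50 observations.

## Known limitations

- The exact AOI rectangle shapes, the authors' software's df conventions,
  and the study's true dropout mechanism are underdetermined by the design;
  the choices above are documented and configurable where they matter.
- The variance grouping supports two levels (the study's case), not a
  general varIdent with k levels.
- Wald F-tests are marginal (drop-one); sequential testing is not
  implemented.
- No image processing: stimuli are catalogue entries, not photographs.
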