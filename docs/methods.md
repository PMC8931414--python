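# Methods

This note documents the generative model behind the synthetic observers, the
estimators in the analysis pipeline, the numerical choices, and the known
limitations — in particular, which properties of real rating data the
simulator does and does not emulate, and therefore what passing recovery
tests do and do not establish.

## Experimental design being modeled

The design crosses two emotions (angry, happy) with three intensity levels
(neutral, weak, strong), two actors per gender and two genders, for both
dynamic face videos and voice clips: 20 faces and 20 voices (5 conditions ×
2 genders × 2 actors).  Audiovisual stimuli pair a face and a voice of the
same gender, and of the same emotion category unless neutral: 2 emotions ×
9 level pairings × 4 actor pairings × 2 genders = 144, with fully neutral
pairings represented once per rated emotion.  Per subject, the unisensory
rating block has 96 trials (emotional stimuli twice on their own emotion
dimension, neutral stimuli four times, twice per emotion dimension), the
multisensory block 144 (each audiovisual stimulus once), and the validation
block identifies each unisensory stimulus once.

Timing metadata follow the stretching rule for pairing a face video with a
voice clip: the final frame is held 500 ms, and the remaining
(duration − 0.5 s) is split evenly over the video's frames (30 frames for
strong, 15 for weak, one static frame for neutral), rounded to the nearest
millisecond.  No media are rendered; timing is metadata only.

## Generative observer model

Per subject *s*, modality *m*, rated emotion *e* and level *l*:

* latent intensity mean μ(m, e, l) = level mean + per-subject offset(m, e) +
  per-stimulus offset.  Level means default to 1.78 / 4.43 / 5.99 Likert
  points (neutral / weak / strong) with a +0.30 offset for emotional angry
  voices — the group means of the rating task the simulator emulates.
* a unisensory trial draws x = μ + N(0, σ_modality) and reports
  clamp(round(x), 1, 7), rounding half away from zero; with probability
  `lapse` (default 0.02) the rating is uniform on 1–7.
* a multisensory trial draws undiscretized face and voice percepts x_V, x_A
  the same way.  The similarity judgment is gated by the **latent**
  difference d = x_V − x_A: either P(similar) = a·exp(−((d − b)/c)²)
  (defaults a = 0.86, b = 0.21, c = 0.88 Likert points, the group
  similarity-curve values) or, with the `threshold` rule, similar iff
  |d| ≤ τ (τ ~ N(2.5, 0.7) truncated to (0.5, 5.5) across subjects).
* the unity state selects fusion weights: rating =
  clamp(round(w_V·x_V + w_A·x_A + c₀ + N(0, σ_M)), 1, 7) with
  w_V + w_A = 1.  Reliance r = w_V − w_A defaults to −0.14 (angry) and
  +0.08 (happy), identical across unity states; `unity_reliance_offset`
  can split them (±offset for unified/segregated) but defaults to 0 — see
  "Selection effects" for why no similarity effect needs to be planted to
  observe one at the analysis level.
* validation responses are correct with per-condition probabilities
  anchored to the observed recognition rates (faces 67.7–97.9%, voices
  53.1–95.3%); errors spread uniformly over the remaining three options.

Between-subject variation: subject intensity offsets SD 0.5 per
(modality, emotion); curve center SD 0.30, width SD 0.20 (floor 0.30),
amplitude SD 0.05; reliance SD 0.20 per condition cell; accuracy jitter
Beta-distributed with concentration 12.  Questionnaire totals are truncated
normals typical of a nonclinical student sample (AQ 17 ± 6 on 0–50, TAS-20
45 ± 10 on 20–100, DASS-21 Depression 8 ± 6, Anxiety 6 ± 5, Stress 10 ± 7
on 0–42) and can be linearly coupled to reliance contrasts (e.g., an
anxiety coefficient on the emotion × unity contrast) for power studies;
all coupling coefficients default to 0.

Noise defaults: trial-to-trial percept noise σ_V = σ_A = 0.3 and
multisensory rating noise σ_M = 0.5 Likert points.  Most rating variance is
deliberately carried by stimulus heterogeneity (per-stimulus offsets,
SD 0.4, drawn once per dataset and shared across subjects — material
properties, not percepts) and subject heterogeneity rather than trial
noise: ratings of fixed stimulus materials are highly repeatable, and the
per-stimulus spread is what gives the audiovisual intensity difference its
quasi-continuous distribution across half-point bins.

Randomness is organized as `SeedSequence` spawn keys per subject and per
block, so enlarging a population or adding a block never perturbs existing
trials.

## What the simulator does not emulate

No reaction times, no order or learning effects, no response styles beyond
a uniform lapse, no emotion-specific unity criteria (the default similarity
curve is shared across emotions, so the default population plants no
angry-vs-happy cut-off difference), and no segregated-percept causal
inference branch (trials judged not-similar still fuse, with their own
weights).  Passing recovery tests therefore shows the estimators are
correct for this generative family, not that real data satisfy it.

## Analysis pipeline

**ΔI.**  Per subject, the mean unisensory rating per stimulus and rated
emotion (2 repetitions); ΔI = face mean − voice mean for the trial's
components on its rated dimension.  Neutral stimuli keep separate means per
rated emotion because the rating question differs.  A condition-level
variant (`delta_granularity="condition"`) is available; per-stimulus is the
default since only stimulus-level means produce the half-point ΔI grid.
Subjects missing a required mean raise a completeness error rather than
being imputed.

**ROC/Youden cut-off.**  Candidates are midpoints between consecutive
sorted unique |ΔI| values plus sentinels 0.25 below the minimum and above
the maximum; classification is similar ⇔ |ΔI| ≤ t.  The Youden maximum is
taken with ties broken by minimum |sensitivity − specificity| and residual
ties by the smallest threshold (the stricter unity criterion); tie metadata
is recorded.  Single-class subjects are flagged in the QC report and
excluded downstream, never fatal.  Equivalence with exhaustive search is
property-tested.

**Similarity curve.**  Signed ΔI is binned into half-open 0.5-point bins
centered on multiples of the width; the group proportion is the unweighted
mean of per-subject proportions (every subject counts equally, matching
SEM-over-subjects error bars).  The scaled Gaussian is fitted by weighted
least squares (weights = per-bin trial counts) via bounded
`scipy.optimize.least_squares` with multistart over centers {−1, 0, 1} and
widths {0.5, 1, 2}; amplitude is bounded to [0, 1], width to > 0; at least
four informative bins are required.  95% CIs come from a nonparametric
bootstrap over subjects (2000 percentile resamples by default; refits start
from the point estimate); a Jacobian-based asymptotic CI is available and
is the automatic fallback when no per-subject bins exist.

**Integration regression.**  OLS per subject and scope over the 3 × 3 grid
of similarity (similar / not-similar / pooled) × emotion (angry / happy /
pooled) scopes; predictors are the subject's per-stimulus unisensory means,
matching the ΔI convention.  Cells need ≥ 5 trials and a full-rank design;
failures are emitted with a reason and logged, and affected subjects are
excluded listwise from the 2 × 2 ANCOVAs.  No regularization.  Estimates
are tested to 1e-8 against the normal-equations solution and statsmodels.

**Contrast-score ANCOVA.**  For 2-level within factors the repeated-
measures ANCOVA is computed exactly in contrast-score form: per-subject
score = weighted sum of condition cells (±0.5 weights for main effects,
±1 for the interaction), regressed on z-scored covariates (sample SD,
ddof = 1, recomputed over the included subjects) with an intercept.  The
intercept F on (1, n − 1 − k) df is the within-subject effect; covariate
slope Fs are the effect × covariate interactions.  With five covariates and
48 subjects the error df is 42.  With k = 0 the procedure reduces exactly
to the paired t-test (F = t²), which is tested to 1e-10, and the type-I
error of the covariate-interaction test is calibration-tested at α = 0.05.
A condition number above 1e8 on the covariate design raises a collinearity
error rather than silently regularizing.  Two-tailed p-values throughout;
no multiple-comparison correction anywhere, by design.

**Reliability-weighted check.**  Pearson correlation between similar-
condition reliance and the face-minus-voice recognition-accuracy advantage,
pooled and per emotion (per-emotion scope restricts the accuracy cells to
that emotion's weak/strong conditions).

## Attenuation and selection effects (important)

The simulator's similarity judgment is driven by the trial's latent percept
difference, while the analysis — like any analysis of real data — only sees
the measured ΔI built from rounded unisensory means.  Two consequences are
intrinsic and worth knowing before interpreting pipeline output:

1. **Attenuation.**  The analysis-level similarity curve is flatter and
   wider than the generative one, and recovered cut-offs are smaller than
   planted thresholds, increasingly so as percept noise grows (mean cut-off
   bias roughly −0.1 at σ = 0.2 up to −0.3 at σ = 0.8 under the threshold
   rule).  Rounding to the Likert grid alone bounds the observable peak of
   the binned curve well below the generative amplitude.  The `recover`
   command quantifies this bias for any configuration.
2. **Selection (Berkson-type) effects.**  Conditioning on the similarity
   judgment restricts exactly the face-voice contrast dimension that
   identifies β_V − β_A, so similar-cell reliance estimates are shrunk
   toward zero by a factor of about 1 − 2σ²/(2σ² + c²/2) before the usual
   errors-in-predictors attenuation.  Two practical corollaries: reliance
   contrasts are best recovered under deterministic gating or low percept
   noise, and an apparent Similarity main effect on reliance arises at the
   analysis level *without any planted difference* between unified and
   segregated weights.

Parameter-recovery tests in the suite therefore isolate stages under
conditions where the proxy is faithful (percept noise 0.2–0.3, hard
threshold gating where cell membership must be clean) and verify estimator
bias properties separately.

## Problem sizes

The test suite and the acceptance script use the study-scale population of
48 subjects (96 + 144 + 40 trials each) for end-to-end runs, 100 seeded
populations for the reliance sign-ordering check, 500 random instances for
ROC oracle equivalence, 10⁴ Bernoulli trials per bin for curve recovery,
1000 replicates for type-I calibration and 10⁵ draws for Monte-Carlo
oracles of the response model — sizes at which Monte-Carlo error is an
order of magnitude below every tolerance asserted.

## Known limitations

* The within-subject ANCOVA is exact only for 2-level factors (the designs
  used here); no sphericity machinery is included.
* Bootstrap CIs resample subjects, not trials, so they reflect
  between-subject uncertainty only.
* The generative similarity curve is modality-difference-based only; real
  unity judgments likely also use identity, timing and semantic cues.
* Planted covariate couplings are linear in the z-scored covariate;
  nonlinear or threshold couplings are out of scope.
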