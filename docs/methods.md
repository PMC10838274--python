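# Methods

This note documents the statistical procedure `gazedpa` implements, the
generative model behind its simulator, and the design decisions taken where
the standard recipe leaves room.

## Data model and conventions

Raw data are *gaze samples*: one row per tracker sample with participant,
item, condition (`negative`, `nobody`, `positive`, `filler`), trial, time in
ms from trial onset, an area-of-interest label (`factual`, `illusory`,
`elsewhere`) and the trial's response correctness.  Samples — not parsed
fixation events — are the counting unit throughout: webcam trackers deliver
samples, and no fixation-event detection is attempted.

Time zero is trial onset.  The default timeline is fixation cross
(0–1500 ms), picture preview (1500–4000 ms), audio over a blank screen
(4000–7000 ms, the **anticipation window**), pictures reappearing from
7000 ms (the **integration window**).  All windows and bins are half-open
`[lo, hi)`, so windows partition the timeline and bins partition the window;
a sample at exactly 4000 ms belongs to the anticipation window.  Filler
trials are parsed but excluded from every analysis by default.

Analyses use correct-response trials only.  Accuracy is summarised per
condition as the mean and sample SD over participants of each participant's
percent correct.

## Per-bin test and onset rule

Within the analysis window, samples are grouped into 200-ms bins per
participant × condition, yielding counts `y_factual`, `y_illusory` and
`n_total` (all samples, including elsewhere).  For each bin, every
participant with `n_total > 0` contributes two observations — the empirical
logit of each target's count against `n_total`:

    elog = ln((y + 0.5) / (n − y + 0.5)),   w = 1/(y + 0.5) + 1/(n − y + 0.5)

A weighted linear model `elog ~ 1 + is_factual` with weights `1/w` is fitted
per bin; the target coefficient is tested one-sided (factual > illusory) at
α = 0.05 against a Student t with (rows − 2) degrees of freedom.  Because the
design is a two-group comparison, the fit has a closed form (difference of
weighted group means); it is implemented as vectorised normal equations so a
full bootstrap evaluates thousands of bins in milliseconds, and the test
suite verifies equivalence with an explicit normal-equation solve and with
statsmodels' WLS to 1e-10.

Choices the recipe leaves open, and what this package does:

* **Rows** are participant-aggregated, not trial-level: one (elog, w) pair
  per participant × target.
* **Bins with `n_total = 0`** contribute no rows (no imputation).  Fewer
  than two contributing participants marks the bin not-significant with an
  `insufficient_data` note — never an exception inside the bootstrap loop.
* The **divergence point** is the *left edge* of the first run of k = 3
  consecutive significant bins (k, α, and one- vs two-sided are
  configurable).  Left edges keep onsets on the bin grid anchored at the
  window start.

## Bootstrap

Uncertainty is quantified by a nonparametric bootstrap of participants:
each replicate draws P participants with replacement (a participant drawn
twice enters as two pseudo-participants), re-runs every bin test and the
onset rule, and records the onset per condition.  One participant draw is
shared by all conditions within a replicate, so between-condition
differences can be formed replicate-wise and the difference distribution is
coherent (its mean equals the difference of means exactly when no replicate
is missing).

* **Missing onsets** (no k-run in a replicate): by default dropped with a
  warning and reported as `n_missing`; alternatively
  `censor_at_window_end` records them at the window's end, which keeps all
  B replicates and is required for null data where most replicates have no
  onset.
* **Intervals**: the percentile CI uses the linear-interpolation quantile
  convention `h = (n−1)p`.  The HDI is the narrowest window of
  `m = ⌈level·n⌉` consecutive order statistics, ties broken toward the
  smaller lower bound.  On bootstrap-sized samples the HDI is never wider
  than the percentile CI (the guarantee needs the CI to bracket at least m
  order statistics, which can fail only for a handful of points).
* **Significance of a contrast**: the 95% CI of the replicate-wise onset
  differences excludes zero.  No correction is applied across the three
  pairwise contrasts.
* **Reproducibility**: one root seed; per-replicate generators come from
  `SeedSequence(seed).spawn(B)`, so replicate b is identical no matter how
  large B is, and a rerun with the same data, configuration and seed
  produces byte-identical JSON output.

## Window summaries, effect sizes, power

Per-trial window proportions are `100 × (samples on AOI) / (all in-window
samples)`; trials with no in-window samples are dropped with a warning.
Condition summaries (mean, sample SD) are computed over trial-level
observations, not participant means — trial-level summaries are what
produces the very large SDs (40–50 on a percent scale) characteristic of
blank-screen data, where single trials are close to all-or-nothing.

Cohen's d uses the equal-weight pooled SD, `d = (m₁ − m₂)/√((s₁²+s₂²)/2)`;
computation is at full precision and only presentation rounds to 2 decimals.
The dependent-means (within-pair correlation) variant is deliberately not
implemented: the pooled form is what published M/SD pairs in this paradigm
reproduce.

`required_sample_size` scans n = 2, 3, … and returns the first n whose
two-tailed paired-t power — computed from the noncentral t distribution with
noncentrality `dz·√n` and n−1 degrees of freedom — reaches the target
(e.g. n = 34 for dz = 0.5, α = 0.05, power 0.8).

## The generative simulator

The simulator emulates a 42-participant × 20-item × 3-condition blank-screen
experiment with known latent onsets, so the whole pipeline can be validated
by parameter recovery without any external data.  Key structure (all
parameters are `SimConfig` fields; values below are the defaults):

* **Latent onsets** τ_c per condition (positive 4200, *nobody* 5600,
  *negative* 6000 ms) plus one normal participant offset δ_p (SD 50 ms).
* **Ramp**: among on-picture looks of an engaged trial, the factual share is
  flat at 0.5 before τ_pc and rises as `2·logistic((t−τ_pc)/s) − 1` (s =
  100 ms) toward an asymptote afterwards, so the unconditional factual
  probability ramps from b = 0.4 to a = 0.72 starting *exactly* at the
  latent onset.  A left-truncated ramp is essential: a logistic centred on
  τ places half its rise before the nominal onset, which would make the
  configured onset unrecoverable by construction.
* **Trial-level lumpiness**, the signature of blank-screen gaze: with
  participant-specific probability (mean ≈ 0.25, SD 0.12) a non-capture
  trial is *disengaged* — all anticipation samples land elsewhere; and
  exactly `round(q·I)` trials per participant × condition (q = 0.3) are
  *capture* trials locked onto one picture, re-locking onto the factual
  (p = 0.9) with probability 0.5 two time constants after τ_pc, the others
  keeping their initial lock all window.  Engaged samples keep a small
  residual elsewhere rate (0.05), chosen so the population elsewhere rate
  during anticipation equals e = 0.2.
* **Accuracy** is Bernoulli(0.99) per trial; preview looks are unbiased
  between the pictures; integration looks favour the factual (0.7).
  Sampling grid 50 ms (a design choice — webcam sampling rates vary).

Three structural choices matter for estimator validity, and are deliberate:

1. Capture-trial *counts are fixed* per cell and their pre-onset lock
   targets *counterbalanced* (half factual, half illusory), mirroring the
   side counterbalancing of real designs.  Independently drawn locks give
   each participant a coherent side bias across all pre-onset bins, which
   participant resampling amplifies into spurious early significant runs.
2. The *shared disengagement propensity* moves both targets' empirical
   logits together.  Without it the two-rows-per-participant model is
   anti-conservative (factual and illusory counts are negatively correlated
   within a bin, violating the independent-rows assumption; measured null
   per-bin t SD ≈ 1.3); with it the residual SE absorbs the shared
   variation and the test is slightly conservative (measured t SD ≈ 0.9,
   per-bin null rejection ≈ 3–4% at nominal 5%).
3. The capture *re-lock lags the onset* by two time constants; an
   instantaneous re-lock leaks systematic signal into the bin before τ via
   participants with negative offsets.

What the simulator does **not** emulate: real blank-screen data show a
baseline preference for the factual already before any detectable
divergence, together with even more extreme trial bimodality (published
trial-level SDs ≈ 44–46 imply nearly pure 0/100 trials).  Those two features
jointly are incompatible with exact recoverability of a configured onset —
a biased baseline plus modest noise triggers the onset rule early — so the
simulator enforces pre-onset exchangeability of the two targets and accepts
trial-level SDs at the lower edge of the published band (≈ 38–44 at
q = 0.5).  Passing recovery tests therefore demonstrates estimator
correctness under a clean latent onset, not performance on data with
baseline bias, item effects (omitted by default), smooth gaze kinematics or
track loss beyond the `elsewhere` category.

## Validation performed by the test suite

* Parameter recovery under defaults (B = 500): each condition's bootstrap
  mean onset within ±200 ms (one bin) of τ_c and the configured ordering
  recovered.  During design this held for 90/90 condition-runs over thirty
  generator seeds (largest error −109 ms).
* Percentile-CI coverage ≥ 85% over 200 reduced experiments
  (12 participants, 6 items, B = 100); measured ≈ 99% — the discreteness of
  the onset grid makes the percentile CI conservative here.
* Type-I control: with a = b and q = 0 the rule reports no onset in ≥ 95% of
  replicates (measured ≈ 98–99%).
* Oracle equivalence of the per-bin regression against explicit normal
  equations and statsmodels WLS to 1e-10; HDI against a brute-force scan;
  power-scan results against statsmodels' solver.
* Determinism: same (data, configuration, seed) → byte-identical artifacts.

Problem sizes in the suite (10–42 participants, B = 30–500, 200 reduced
replica experiments) were chosen so the full run finishes in well under a
minute while keeping every check at the scale its property needs.

## Known limitations

* The percentile bootstrap of a discrete onset estimator yields stepped,
  sometimes degenerate intervals (e.g. `[5600, 5600]`); the HDI is reported
  alongside but no continuity correction is applied.
* The per-bin model treats a participant's two rows as independent; on data
  without shared participant-level variation it is mildly anti-conservative
  (see above).  Cluster-mass permutation or GAMM-based alternatives are out
  of scope.
* Mixed-effects modelling of window proportions is intentionally delegated:
  the pipeline exports a tidy trial-level table for external fitting.
* No raw eye-tracker formats, fixation parsing, drift correction or
  graphics.
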