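# Methods

`newstrf` implements an analysis pipeline for EEG recorded while
participants listen to affective news broadcasts, together with a
synthetic-cohort generator that provides a ground-truth test surface for
every stage.  This note describes the models, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data do and
do not establish.

## The encoding model

Natural speech gives no clean inter-trial intervals, so word-locked
responses are estimated as a temporal response function (TRF): the
continuous response at channel *ch* is modeled as a convolution of a
binary content-word impulse train s(t) with an unknown weight curve,

    r_ch(t) = Σ_τ w_ch(τ) s(t − τ) + ε_ch(t),

over lags τ ∈ [−100, 800] ms.  Weights are estimated per trial by ridge
regression on the lagged design matrix (181 columns at 200 Hz).  Design
choices:

- **No intercept, no column scaling.** The regressors are 0/1 impulses on
  a common scale; plain ridge with an identity penalty is used.
- **Zero-padded edges.** Lagged copies of the stimulus are zero-padded at
  trial boundaries, consistent with impulse-train semantics.
- **Penalty selection.** Per subject, leave-one-trial-out CV over the grid
  {2¹ … 2²¹}: single-trial weights are fit on the training trials,
  averaged, and scored by MSE on the held-out trial, averaged over
  held-out trials and channels; ties go to the smaller λ.  A single
  population λ* — the mode of the per-subject winners, ties again toward
  the smaller value — is then used for every subject's final TRFs, which
  are condition-wise means of single-trial fits.  λ* is re-estimated from
  each dataset rather than hard-coded, because its value is
  dataset-specific.
- **Unequal trial lengths** (45–83 s) are used at native length; MSEs are
  averaged per trial, then across trials, unweighted.

A practical observation about the CV curve: because the estimator averages
the 14 training trials' single-trial fits, the averaging itself acts as a
strong variance reducer.  At moderate noise (≥ −10 dB per-word SNR) the
CV-MSE is monotone in λ and the grid floor wins; a U-shaped curve with an
interior winner appears only at the very low per-word SNR (around −20 dB)
characteristic of real speech EEG, where single-word responses are far
below the background.  The interior-selection property test therefore runs
at −20 dB.

## Preprocessing

The chain mirrors a standard speech-EEG pipeline: 1–50 Hz FIR band-pass
(order 3300 at the native 500 Hz), resampling to 200 Hz (polyphase),
transient-artifact handling, then a 1–8 Hz FIR band-pass (order 1320,
designed at 200 Hz since it follows resampling).  Two deliberate choices:

- **Zero-phase application.** FIR filters are applied by centered
  convolution of the symmetric impulse response (exact group-delay
  compensation).  Latency measures would otherwise be biased by half the
  filter order.
- **Threshold interpolation instead of subspace reconstruction / ICA.**
  Transient large-amplitude windows (default 100 µV, 200 ms windows) are
  replaced by linear interpolation and logged; a trial with more than half
  its samples rejected is flagged unusable but not silently dropped —
  exclusion is a dataset-level decision.  Subspace reconstruction and
  ICA-based ocular cleaning are published external methods and are out of
  scope; the amplitude-threshold surrogate is sufficient for the
  synthetic data, which contain no ocular artifacts.

## Component measures

Amplitudes are window means of the TRF weight curve — N1 [100, 160] ms,
P2 [170, 230] ms, N400 [300, 600] ms, endpoints inclusive on the 5 ms lag
grid.  Latencies are obtained per subject by dynamic time warping (DTW):

1. the grand-average (GA) curve per channel × condition is computed with
   equal subject weights;
2. the GA's polarity-appropriate extremum (minimum for N1/N400, maximum
   for P2; ties to the earliest lag) is located inside the component's
   amplitude window;
3. the subject curve is warped onto the GA with local cost |a−b| on
   per-curve z-scored series, symmetric unit steps (1,0)/(0,1)/(1,1), no
   warping window; z-scoring makes the alignment amplitude-invariant;
4. the subject's latency is the mean lag of the subject samples the
   optimal path maps onto the GA peak sample — deterministic and robust
   to path plateaus.

The classifier's feature table carries 12 EEG features (N1/P2 peak latency
at Fpz and N1/N400 mean amplitude at Pz, each per news condition) and 6
rating features (per-subject condition means of arousal and
comprehensibility).  Cz latencies are computed and reported but do not
enter the classifier.

## Group statistics

Each measure enters a two-way mixed ANOVA (between: depressed /
non-depressed by BDI-II ≥ 14; within: negative / neutral / positive news).
Because the groups are heavily unbalanced (e.g. 32 vs 103), between-cell
sums of squares use the unweighted-cell-means convention with the
harmonic-mean group size; the within error is the residual after removing
subject intercepts and cell profiles.  Partial η² = SS_effect /
(SS_effect + SS_error).  Greenhouse–Geisser ε is computed from the pooled
within-measure covariance and always reported with the original degrees
of freedom; the ε-adjusted p replaces the unadjusted one only when
Mauchly's test rejects sphericity at 0.05.

Subjective ratings (ordinal 1–5) are aligned-rank-transformed before the
ANOVA: for each effect, every observation is stripped of all estimated
effects except the target (unweighted cell-mean decomposition) and the
aligned values are midranked; one ANOVA is run per effect on its own
ranked response.  EEG measures enter untransformed.

Post-hoc families: paired t-tests across condition pairs when the News
main effect is significant (per group when the interaction is
significant), and unpaired t-tests between groups per condition; p-values
are Bonferroni-multiplied by the family size and clamped at 1.  The
participant-table checks use the asymptotic chi-square test of
independence (no continuity correction) with Cramér's V, and the
pooled-variance independent t-test with Cohen's d.

## Detection of depressed individuals

Leave-one-subject-out CV over three feature sets (12 EEG / 6 rating / 18
combined).  Per fold, strictly on the training rows: features are
standardized (constant columns scale by 1); for the EEG and combined sets,
recursive feature elimination drops the smallest-|coefficient| feature one
at a time until 6 remain (elimination fits use C = 1, ties drop the later
column); the cost C is chosen from {10⁻³ … 10³} by stratified 3-fold
accuracy of class-weighted fits (ties to the smallest C); the final model
is a class-weighted squared-hinge L2 linear SVM, class weight
N/(K·n_k).  The held-out subject is scored by its decision value; pooled
scores give the ROC AUC (ties count ½) and signed scores give the
confusion counts.

The SVM is solved in the primal by damped Newton iterations on the
liblinear objective (regularized intercept via an appended constant
feature).  The objective is piecewise quadratic and strictly convex, so a
handful of iterations reach machine precision; the test suite cross-checks
the coefficients against scikit-learn's `LinearSVC` on randomized
problems.  The in-package solver keeps the permutation test — which
re-runs the entire LOOCV pipeline (standardization, RFE, grid search,
fitting) for each of 1000 label randomizations — tractable on one CPU.

Permutation significance uses the (b+1)/(m+1) convention: with 1000
randomizations the smallest attainable p is 1/1001 ≈ 0.001.  The literal
proportion b/m would report 0 when the observed AUC beats every null,
which is not a valid p-value.  One label shuffle is drawn per
randomization and reused across all folds of that randomization's LOOCV,
preserving the dependency structure of the observed statistic.  Reported
coefficients are mean |coefficient| across folds with zeros for unselected
features, min-max normalized to [0, 1].

## The synthetic cohort

The generator emulates the study design: two groups (default 32 depressed
/ 103 non-depressed, BDI-II drawn from N(21.1, 8.6²) clipped ≥ 14 and
N(6.6, 3.3²) clipped < 14), 15 news items (5 per condition) with fixed
durations drawn from U(45, 83) s, shared word-onset annotations, three
channels, and 1–5 ratings.

- **Word onsets**: a jittered renewal process — 150 ms floor plus an
  exponential tail keeping the mean gap at 1/rate (default 2.5 words/s, a
  plausible broadcast-speech rate, configurable because transcript word
  counts are not part of the study record).  Onsets are confined to
  [0.5 s, duration − 1 s] so each word's full 800 ms response fits in the
  trial.
- **Kernels**: Gaussian bumps, N1 (−5 µV, 130 ms peak, 40 ms FWHM), P2
  (+5 µV, 200 ms, 50 ms), N400 (−6 µV, 420 ms, 180 ms) — smooth,
  window-compatible, with analytically checkable extrema, at ERP-scale
  microvolt amplitudes.  Channel mixtures follow auditory-ERP topography:
  N1/P2 dominant at Fpz, N400 at Pz, everything at Cz.
- **Noise**: per-channel independent 1/f ("pink") noise band-limited to
  1–50 Hz, scaled per trial so the kernel-train-to-noise power ratio
  matches the configured SNR exactly (default −10 dB).
- **Injected effects** (all multiplied by `effect_scale`; 0 gives an
  exact null cohort): +21 ms N1 and +27 ms P2 latency for the depressed
  group on positive news; N400 latency 33.3 ms earlier for negative than
  positive news in both groups; N400 amplitude gain ×1.4 for the
  depressed group on negative news; N1 amplitude gain ×1.3 for the
  non-depressed group; arousal −0.3 and comprehensibility −0.4 latent
  shifts for the depressed group.  Between-subject variability: latency
  jitter SD 8 ms, log-normal amplitude gain SD 0.1, rating intercept SD
  0.3.
- **Ratings**: latent Gaussians per (scale, condition) with means
  following the news-set profile (valence 1.8/3.2/3.9 for
  negative/neutral/positive, arousal 3.1/2.8/3.0, interest 3.1/2.7/2.8,
  comprehensibility 3.7/3.4/3.9; latent SD 0.7), rounded and clamped to
  {1…5}.

Ground truth — per-subject realized kernel parameters and the configured
population means — is serialized next to the cohort and never read by any
analysis stage.

**What the synthetic data do not show.** The generator has no ocular or
movement artifacts, no volume conduction, no inter-channel noise
correlation, no speech audio, and Gaussian component kernels rather than
empirically shaped ones.  Passing tests therefore establish that the
pipeline recovers what it assumes — linear word-locked responses in 1/f
noise — not that the study's specific effect sizes would replicate on new
recordings.  One consequence of the kernel family worth knowing: when the
N1 latency is shifted alone while P2 stays put, the 1–8 Hz band-pass
blends the overlapping bumps and the apparent trough shift is attenuated
to roughly half; when N1 and P2 shift coherently (as the study reports and
the default effect plan injects) recovery is accurate.

## Problem sizes used in tests

The suite runs scaled-down cohorts (7–20 subjects, 18–40 s trials
generated directly at 200 Hz, FIR orders reduced proportionally for the
shortest trials) and the statistical-calibration suites draw rating-level
replicates directly from the ratings model (500 ANOVA replicates, 50
LOOCV replicates).  The acceptance script uses 40 subjects (10/30) at full
trial lengths with the complete 1000-randomization permutation test.

## Known limitations

- The ANOVA's unweighted-means convention is one of several defensible
  choices for unbalanced mixed designs; software packages differ and F
  values on strongly unbalanced data will differ accordingly.
- Mauchly's test uses the asymptotic chi-square approximation, which is
  anticonservative for very small samples.
- The DTW latency is the mean lag of subject samples aligned to the GA
  peak; for pathologically flat subject curves the warp path plateaus and
  the latency regresses toward the window center.
- `grid_search_c` requires at least 3 training members per class
  (stratified 3-fold); cohorts with fewer depressed subjects cannot be
  classified.
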