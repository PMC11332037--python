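# Methods

This note documents the models, scoring rules and numerical conventions the
package implements, the design choices made where several defensible options
existed, and what the synthetic generator does and does not emulate.

## Phasic electrodermal scoring

Raw EDA (µS, nominally 1 kHz) is band-pass filtered with a 2nd-order
Butterworth applied forward–backward (zero phase, so onset alignment is
preserved), 0.0159–5 Hz for phasic scoring. Epochs span [−2, +6] s around
cue and heat onsets with closed endpoints — at 100 Hz after decimation that
is 801 samples with the onset at column 200. Decimation picks the nearest
source sample; the preceding 5 Hz low-pass makes this equivalent to proper
resampling.

Outlier trials are removed with a jack-knife rule: trial *t* is excluded iff
any of its samples deviates from the leave-trial-*t*-out pooled mean by more
than 4.89 leave-*t*-out SDs (sample SD, ddof 1), computed separately per
epoch type and participant. The leave-out unit is the whole trial: exclusion
decisions are per trial, and letting a trial contribute to its own threshold
would be circular. Fewer than three usable trials disables the rule with a
warning.

The per-trial score is peak-to-peak: the maximum *m* over [onset+3 s,
onset+6 s] (first maximum on ties), then the minimum *v* over [onset, τ]
where τ is the time of *m*. Because τ belongs to the min window, `m − v ≥ 0`
always. Values below 0.02 µS are floored to 0, and the transformed score is
the natural log of (1 + raw) — base e because no base is conventional and
the natural log is the analysis-package default.

## Facial action units

Eight OpenFace-style intensity channels (AU04, 06, 07, 09, 10, 12, 25, 26)
are combined frame-wise into a pain-expression composite
`AU04 + max(AU06, AU07) + max(AU09, AU10) + AU12 + max(AU25, AU26)`.
Frames with failed face detection are missing and propagate to the
composite. Epochs span [−1, +3] s; the score is the maximum composite over
the half-open window (onset, onset+3 s]; epochs with no valid frame are
excluded and treated downstream exactly like EDA outlier exclusions.

For the secondary (phasic) models, sequential per-cue trial pairs are
averaged — trials 1–2, 3–4, 5–6 — yielding a three-level Trial factor; a
pair with one excluded member keeps the surviving value, so single-trial
exclusions rarely cost a cell.

## Cross-recurrence quantification (physiological synchrony)

Each member's block-length EDA is band-passed 0.05–1 Hz, downsampled to
8 Hz, and z-scored. Unequal lengths are truncated to the shorter series.
The two series are delay-embedded with shared parameters:

* **delay** — first local minimum of average mutual information (16-bin
  histogram estimate), averaged over the two series, capped at 40 samples
  (5 s at 8 Hz);
* **dimension** — smallest m ≤ 10 whose Kennel false-nearest-neighbour
  fraction (Rtol 10, Atol 2) is below 10% on both series;
* **radius** — Euclidean norm; RR(r) is exactly the empirical CDF of the
  cross-distance distribution, so the radius is solved directly as the
  distance quantile at the 3% mid-target, with bisection as a fallback for
  tie-heavy distributions. The achieved RR is stored and always lies in the
  2–4% band or an error is raised.

The cross-recurrence matrix marks (i, j) recurrent iff
`‖x_i − y_j‖ ≤ radius`. DET is the fraction of recurrent points on diagonal
runs of length ≥ 2, LAM the analogue for vertical runs (minimum line
lengths of 2 are the reference defaults in the recurrence literature). No
Theiler window is applied: cross-recurrence between two people has no
trivial self-matches. DET/LAM are undefined (NaN) when RR = 0. With 0.05–1 Hz
content sampled at 8 Hz the series are strongly oversampled, so both
measures sit near the top of their range and are left-skewed across dyads;
the across-dyad transform is therefore `z(exp(value))` with DET/LAM on the
proportion (0–1) scale, which pulls the skew toward symmetry before
standardisation.

## Psychological synchrony and responder classification

Psychological synchrony is the product-moment correlation (rank correlation
available as an option) between demonstrator and observer expectancy ratings
across the 12 trials, pairwise-complete; dyads with fewer than 3 usable
pairs or zero variance in either member are excluded.

The responder test permutes cue labels within subject, preserving the 6/6
split (10,000 Monte-Carlo draws by default; exact enumeration over all
C(12,6) = 924 relabellings as a flag). The statistic is mean(Tx) − mean(NT);
p-values use the add-one estimator with ties counted toward the null, so
they are valid and never zero. One-sided p ≤ 0.05 in the upper tail gives
"responder", in the lower tail "reverse-responder", otherwise
"non-responder". Responder proportions across generations are compared with
Pearson χ² (no continuity correction) and Cramér's V = √(χ²/N).

## Mixed ANCOVA

The split-plot ANCOVA (Cue × Trial within; Generation between; a
subject-constant covariate) is computed stratum-wise. Per-subject cell means
are projected onto orthonormal within-subject contrasts; each stratum's
scores are regressed on the between design (intercept, effect-coded group,
centered covariate), and each effect is tested with the pooled univariate F
— Type III, no sphericity correction, hence integer degrees of freedom
(e.g., F(1, N−3) for Cue, F(5, 5(N−3)) for a 6-level Trial). A stratum whose
total sum of squares vanishes (identical Tx and NT cells) has F = 0 by
convention. Subjects missing any cell are dropped listwise and reported.

Effect sizes are partial η² = SS_eff/(SS_eff+SS_err) with 95% CIs from
two-sided inversion of the noncentral-F CDF. Adjusted marginal means for Cue
come from an OLS fit of the per-subject cue means on the between design:
with effect coding and a centered covariate the intercept is the
equal-weight covariate-adjusted mean, with its OLS standard error and t
interval; the adjusted Tx−NT difference is estimated the same way from the
per-subject difference scores.

Coding conventions: Generation G2 = +1, G3 = −1 (effect coding — the unique
convention under which a main effect B and interaction B reproduce
conditional slopes as B ± B_int); gender match = ±0.5, centered.

## Hierarchical regression and simple slopes

Stages are nested OLS fits on a single complete-case sample determined by
the final stage's predictors (so coefficients are comparable across stages).
Reported per predictor: B, SE, t, p, 95% CI, and standardised
β = B·sd(x)/sd(y). Collinearity beyond condition number 1e8 on the
standardised design raises an error. Simple slopes of a focal predictor at
moderator level m are B_focal + m·B_interaction with a delta-method SE from
the coefficient covariance and a t interval on the residual df; for
continuous moderators the default levels are the mean and ±1 SD.

## Synthetic generator

The generator emulates the study's structure so that every pipeline stage
has realistic input: 3-generation chains, 12-trial blocks with 6 Tx/6 NT
cues under the pseudorandomisation rules (max run 3, 2–4 per half,
transitions from each cue split as evenly as possible), 45/54 °C for G1 and
45 °C throughout for G2/G3, trial timing matching the procedure (2 s
fixation, 6 s cue, 6 s expectancy window, 7–10 s ITI to heat, 12 s
inter-trial interval), and a 50% pain-rating display schedule (first Tx and
first NT always shown, three per half, never more than two in a row). Cue
sequences are sampled uniformly from the exhaustively enumerated valid set
(230 of the 924 label placements).

**Ratings.** Demonstrator pain = nociceptive baseline per temperature (36 at
45 °C, 75 at 54 °C) + a cue-contingent nocebo shift + N(0, 10) noise,
clipped to [0, 100]. The shift is `sign(responder type) × effect`, where the
effect defaults to 7 VAS points and may depend linearly (4 VAS per SD) on
the coupling of the dyad the subject observed in — this is what links
synchrony to subsequent nocebo magnitude. Responder types mix 44%
responders, 46% non-responders, 10% reverse-responders (negative shift).
Observers update per-cue expectancies with a delta rule (rate 0.5) on the
demonstrator's expressed pain, at half weight when the rating is suppressed
and only the face is available; the weighting of ratings vs faces is a free
parameter, not an estimated quantity. 8.2% of expectancy ratings are deleted
at random.

**Electrodermal signals.** Each member's EDA is a baseline level plus a
per-subject gain times a latent arousal mixture `κ·shared + √(1−κ²)·own`,
plus stimulus-locked SCRs and white measurement noise. Each latent arousal
path is a stationary Ornstein–Uhlenbeck process (τ = 3 s, so its power lies
inside the 0.05–1 Hz synchrony band) plus a Poisson train of spontaneous
SCR-shaped bursts (0.15 Hz ≈ 9/min, median 0.5 µS). The burst component is
deliberate: a purely Gaussian κ-mixture leaves CRQA's DET flat because
diagonal-line structure depends only on each series' smoothness, whereas
shared bursts give coupled dyads matched state-space excursions that DET can
see. Stimulus SCRs use a Bateman bi-exponential kernel (rise 0.75 s, decay
2 s, latency 1 s), amplitudes scaled by felt (demonstrator) or observed
(observer) pain with lognormal jitter whose log-scale fluctuations are
correlated κ across the dyad — empathic coupling of response magnitude.
Anticipatory cue-locked SCRs scale with current expectancy.

**Facial channels.** A pain-expression trace (fast-kernel bumps at cue and
heat onsets, scaled by expectancy and felt/vicarious pain) is split across
the eight AUs with fixed weights such that the noise-free composite equals
the trace; 2% of frames are dropped as failed detections.

**What passing tests do and do not show.** The generator produces the
*statistical structure* the analysis assumes — coupled arousal, SCR-shaped
phasics, learning-driven expectancies, responder heterogeneity — not
biophysically faithful skin conductance, facial dynamics, artifacts or
non-stationarity. Tests passing on synthetic sessions validate the pipeline's
correctness and calibration under those assumptions; they do not certify
effect sizes on real recordings. In particular, the DET–coupling association
under the fixed measurement chain (0.05–1 Hz, 8 Hz, RR fixed at 2–4%,
minimum line length 2) is real but small (≈+0.002 DET between weakly and
strongly coupled dyads, per-dyad SD ≈ 0.004), because band-limited smoothness
saturates line formation; the monotonicity test therefore compares 50 dyads
per coupling level.

## Problem sizes and determinism

All randomness flows through numpy Generators seeded explicitly; identical
seeds give bit-identical sessions and pipeline tables. The simulation
studies run at the following sizes, chosen to estimate each quantity with
comfortable Monte-Carlo margin: recurrence-rate targeting over 50 dyads at
the default 1 kHz; classifier calibration over 2,000 null subjects × 10,000
permutations; coupling-effect sign recovery over 200 replicates of 60
dyads (ratings-level simulation); ANCOVA interval coverage over 500
replicates of 66 subjects. The coupling-monotonicity check simulates EDA at
100 Hz — the analysis band ends at 1 Hz, so the acquisition rate affects
cost only.

## Known limitations

* The on-disk dialect of externally deposited datasets differs from the
  generator's layout; the reader's column maps must be adapted before
  external reproduction.
* DET/LAM operate close to their ceiling under the fixed measurement chain;
  between-dyad contrasts are carried mostly by the exp/z transform of small
  differences.
* The mixed ANCOVA supports exactly two between-subject groups (the design's
  G2/G3 contrast) and a single subject-constant covariate.
* Observer expectancy updating treats suppressed-rating trials with a single
  attenuation constant; no trial-wise gaze or attention model is attempted.
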