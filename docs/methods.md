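# Methods

This note documents the models and numerical choices behind `breathloop`:
what each stage computes, which parameters matter, what the synthetic
cohort emulates (and does not), and where the design was genuinely open.

## The breathing biofeedback score

The training rewards slow, deep diaphragmatic breathing. Every 2 s
(0.5 Hz update rate) the last 30 s of the respiration-belt signal are
analyzed by spectral density estimation, and the feedback score is the
spectral power inside the 6–10 breaths/min band (0.1–0.1667 Hz) relative
to total power:

    score = P[0.1, 0.1667 Hz] / P_total  ∈ [0, 1].

A raw in-band/out-of-band ratio r is unbounded; in-band/total is its
bounded monotone transform r/(1+r) and preserves the documented [0, 1]
range, so we use it as the score definition. Because power is an area
under the spectral curve, the score responds to breathing *depth* whenever
any fixed-amplitude noise floor is present (deeper breathing raises
in-band area against the fixed broadband floor) and to *pace* through band
membership. The rewarded target pace is 8 breaths/min, the band center.

Numerical pipeline (per 30 s window):

1. linear resampling to a uniform 10 Hz grid (belt rates vary; 10 Hz is
   far above twice the band's upper edge);
2. mean removal, then a Hann taper;
3. zero-padding to a 1024-point FFT, giving a ≈0.0098 Hz grid — a raw
   30 s window resolves only 0.033 Hz, too coarse against a 0.067 Hz-wide
   band;
4. one-sided periodogram with density scaling (integral recovers segment
   variance to within a few percent under the taper) and rectangular band
   integration, DC excluded.

Degenerate inputs: a window whose variance falls below 1e-10 relative to
its mean-square scale scores 0 (flat-signal convention). No scores are
emitted before one full window of data exists; the first score sits at
t = 30 s.

Baseline summary: baseline recordings vary in length, so the shortest
recording in the cohort — 29 score samples at 0.5 Hz, spanning 56 s by
interval counting — is the length reference; longer baselines contribute
only their last 29 samples to the baseline mean.

## HRV spectra and breathing–HRV coherence

R–R intervals outside 300–2000 ms are treated as detection artifacts and
removed (beat times of retained intervals are kept, leaving gaps); a
session losing more than 20 % of beats is marked unusable rather than
repaired. The cleaned series is interpolated with a cubic spline onto a
uniform 4 Hz tachogram — standard HRV practice — and Welch power (60 s
Hann segments, 50 % overlap, ≈0.017 Hz resolution, ≥ 4 averaged segments
in a 15-min session) is integrated over the low-frequency (0.04–0.15 Hz)
and high-frequency (0.15–0.40 Hz) bands.

Slow paced breathing near 8 breaths/min (0.133 Hz) drives respiratory
sinus arrhythmia into the LF band, so breathing-driven HRV is summarized
as the *mean magnitude-squared coherence* between the breathing trace and
the tachogram over the LF band, both on a common 4 Hz grid. The band mean
(not the band max) is used: it is the stabler summary and makes the
estimator's bias explicit — for independent signals Welch-averaged MSC has
expectation ≈ 1/L with L averaged segments, which the tests assert
directly. With the default Mayer-wave and period-noise terms active the
band mean sits near 0.7 even under strong RSA, because band bins without
breathing power dilute the mean; the RSA-isolation checks therefore switch
those terms off, where coherence exceeds 0.9.

Mean heart rate uses the time-domain convention 60000/mean(RR ms);
heart-rate change is the mean in-game HR minus the mean baseline HR.

## Behavioral metrics

Hits, misses, false alarms and correct rejections tally the resolved
hostile/friendly targets per session. Sensitivity and bias follow
equal-variance signal detection theory with a loglinear (Hautus)
correction applied unconditionally — 0.5 added to each count, 1 to each
denominator — so sessions with empty cells yield finite z-scores:

    H = (hits + 0.5)/(hostile + 1),  F = (fa + 0.5)/(friendly + 1),
    d′ = z(H) − z(F),                c = −[z(H) + z(F)]/2.

The criterion uses the standard sum form; a difference form would make
c ≡ −d′/2, collapsing bias into sensitivity, which contradicts their
observed independence. The priming effect is the raw (uncorrected)
false-alarm-rate difference between primed and unprimed friendly targets;
it is undefined (missing) when a stratum is empty. "Control of the self"
is the percentage of post-warm-up session time with score ≥ 0.8, and the
awareness score is actual minus self-reported control (negative =
overestimation).

## Withdrawal-design statistics

The ten-session ABBABABABA design (A = sessions 1, 4, 6, 8, 10 without
biofeedback; B = 2, 3, 5, 7, 9 with) yields per subject four *addition*
(A→B) and four *removal* (B→A) consecutive-session contrasts — 36 of each
across nine subjects. Each session's score stream is reduced to 15 s bin
means; only complete bins count, and the first two bins are discarded to
keep baseline-period data out of the analysis (a 15-min session leaves 58
bins).

Non-overlap of a contrast uses the cross-pair Kendall's tau

    tau = (C − D)/(n_i · n_j),

counting concordant (later session higher) and discordant cross-session
bin pairs; ties count in neither. This variant spans exactly [−1, 1] —
complete separation gives |tau| = 1 — whereas the tie-corrected tau-b has
a ceiling near 0.71 for balanced ~58-bin samples; tau-b remains available
as an option. No Theil–Sen baseline-trend correction is applied: within-
session trends in these data are typically negative and correcting for
them would manufacture false positives. Two-sided p-values come from the
tie-corrected Mann–Whitney normal approximation (cross-pair tau is a
linear function of the Mann–Whitney U). Per direction, contrasts merge
into a meta effect as the pair-count-weighted (w = n_i·n_j) mean tau, with
a matching weighted Stouffer combination of signed z-scores for the meta
p-value; both choices are configurable, as the combination method is
conventional rather than forced.

**Calibration and its limits.** On independent bins the contrast test is
well calibrated (type-I error 0.05 ± 0.02 at α = 0.05; asserted over
2,000 simulated 58-bin null pairs). Through the full pipeline, however,
consecutive 15 s bins average scores whose 30 s windows share up to 28 s
of breathing data; the resulting lag-1 bin-mean autocorrelation (~0.4)
violates the rank test's independence assumption and inflates the
realized null rejection rate to roughly 0.10–0.13. This is a structural
property of any bin-level non-overlap test applied to sliding-window
scores, not an implementation artifact; a test pins the direction of the
effect (pipeline null rate > i.i.d. null rate). Real-data contrasts
should be read with this in mind — the large effects the training
produces (|tau| near 1) dwarf it, but borderline significance does not
survive it.

Six-feature visual analysis: per phase change, level (phase-mean
difference), trend (slope difference, per bin), variability (SD ratio),
immediacy (first 3 bins of the new phase vs last 3 of the old), overlap
(significant tau with the expected sign), and consistency
(within-direction SD of phase means versus the A–B separation). A feature
registers a "change" when it moves in the intervention-predicted
direction by at least a documented threshold (level/immediacy 0.05 score
units; trend 0.002 per bin; variability ratio 1.25 or its reciprocal) —
conventional operationalizations, configurable. The intervention decision
requires ≥ 3 changes on ≥ 3 of the six features.

Repeated-measures correlation: both variables are centered on subject
means and the pooled residuals correlated; df = n_obs − n_subjects − 1,
p from the t distribution. Incomplete pairs are dropped listwise and
subjects with fewer than two complete pairs are excluded (a single pair
carries no within-subject information). The implementation is checked to
1e-10 against a dummy-variable regression oracle and against
`pingouin.rm_corr`.

## The synthetic cohort

The real training cohort is not redistributable, so a generator produces
9 subjects × 10 sessions with known ground truth. Defaults are the study
conditions: 900 s sessions (≈15 min) in 14 waves of 8 targets, a 60 s
rest baseline (belt worn one analysis window earlier so the baseline
score stream covers the full rest period, ≥ 29 samples), and an in-game
heart-rate rise of +10 bpm over a 75 bpm baseline, matching the observed
arousal response.

* **Breathing**: a phase-continuous chirp (integrated instantaneous
  frequency; no spectral seams at pace changes), depth 1.0 belt units,
  breath-level pace jitter SD 1 bpm, additive white noise floor SD 0.25.
  A subject's pace mixes the 8 bpm target and a 14 bpm unpaced rest rate
  according to adherence.
* **Learning**: adherence gains accumulate at 0.05 per session, B
  sessions add a 0.30 boost (the biofeedback effect), A sessions retain
  60 % of accumulated gains (transfer); subjects get small seeded
  perturbations (SD 0.04). Adherence is deterministic per
  subject-session, so with learning and boost at zero, session bins are
  exchangeable — the null-calibration condition.
* **Cardiac**: integrate-and-fire (IPFM-style) beat emission over an
  instantaneous heart period 60000/HR + 40 ms·z(t) (RSA on the normalized
  breathing signal) + 15 ms Mayer wave at 0.1 Hz + slow noise (SD 10 ms,
  1 s knots). Integration, rather than direct interval perturbation,
  makes the tachogram stage do real work. Realized mean HR lands within
  2 % of target.
* **Observer**: equal-variance Gaussian evidence (friendly N(0, 1),
  hostile N(d′, 1)), shoot when evidence > d′/2 + c, with d′ = 1.5,
  c = 0.3, and a 0.4 criterion drop for targets matching the announced
  (primed) body type. The body-type identifier's reliability declines
  linearly from 100 % (wave 1) to 50 % (wave 14); eye color always
  identifies hostiles. Parameter-recovery checks run the pure observer
  (priming bias 0), since with the bias active the pooled session is a
  mixture observer whose d′ exceeds the generating value by construction.
* **Self-ratings**: reported control-of-self equals actual plus an
  overestimation that decays geometrically (30 % → ≈1 % across ten
  sessions, noise SD 5), reproducing the early-overestimation/late-
  accuracy awareness pattern.

One master seed fixes everything (hierarchical seed sequences), so
cohorts are byte-reproducible. What the generator does **not** emulate:
motion artifacts and ectopic-beat morphology (only out-of-range intervals
for the artifact screen), postural/thermoregulatory HRV drift,
within-session fatigue, target spawn geometry, or any dependence of
behavioral performance on breathing state. Passing recovery tests
therefore show the *pipeline* is correct and well calibrated under the
stated signal models — not that real respiration belts or chest straps
behave this way.

## Problem sizes used in tests

Statistical tests run at sizes chosen for stable assertions: 2,000 null
pairs for the i.i.d. tau calibration; 500 subjects with 240 s sessions
(14 bins) for the pipeline-level null rate; 100 sessions for d′/criterion
recovery; 600 s traces for coherence checks; the full 9 × 10 cohort at
900 s for end-to-end recovery and reporting.

## Known limitations

* The spectral estimator (Hann taper, 1024-point zero-padded
  periodogram) is a documented choice; the original real-time system's
  exact estimator is not claimed to be identical, and neither are the
  coherence estimator's segmenting choices.
* The instructed pace in the source protocol (5 s in / 5 s out = 6 bpm)
  differs from the rewarded 8 bpm; both lie inside the scored band, and
  the package takes no position — the band, not the target, defines the
  score.
* Bin-level non-overlap inherits the sliding-window autocorrelation
  discussed above; per-contrast p-values are anti-conservative through
  the pipeline.
* Wave composition (targets per wave, spawn timing) is not documented in
  the source protocol and is configurable with the defaults above.
* "Control of the situation" and "control of the suspect" scores are out
  of scope; the session schema reserves no computation for them beyond
  the stored self-ratings.
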