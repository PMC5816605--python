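# Methods

`dyadsync` analyses social physiological compliance (SPC) — the synchrony of
autonomic signals between interacting people — in collaborating dyads
recorded in a shared room, with pair programming as the motivating setting.
This note documents the models, the estimators, the synthetic-data generator
that stands in for recorded classroom data, and the numerical and design
choices that were genuinely open.

## Signals and feature tracks

All analysis happens on 1 Hz feature tracks aligned to a common session
clock (second 0 = start of the baseline period). Missing seconds are
explicit NaNs, never dropped, so tracks stay aligned across participants.

**Cardiac features.** The input contract starts at R-peak times (beat
detection is upstream). Inter-beat intervals (IBIs, ms) are screened for
abnormal beats — outside 300–2000 ms or more than 30% from an 11-point
running median — before windowing; the screen is configurable because the
HRV literature states the normal-to-normal requirement without a single
criterion. Windowed mean HR (`60000 / mean IBI`) and SDNN (sample standard
deviation of IBIs, n−1 divisor) are computed in 60 s and 300 s half-open
windows anchored at second 0, stepping by two-thirds of the window (20 s and
100 s: one-third overlap). An IBI belongs to the window containing its
terminating beat; windows with fewer than two usable IBIs are missing, not
errors; windows that would extend past the last beat are not emitted. Window
values are step-hold upsampled to 1 Hz (no interpolation — causality is
preserved and only information the window already contains is repeated).
Instantaneous heart rate HR1 is `60000 / mean(IBIs terminating in that
second)`, forward-filled over beatless seconds for at most 3 s before being
flagged missing: bounded fill prevents long fabricated runs.

**Electrodermal activity.** Raw skin conductance (nominally 51.2 Hz) is
modelled as `raw = SCL + SCR + residual`, with `SCR = (driver ⊛ h)` for a
sparse non-negative driver (sudomotor nerve activity, treated as a density
in µS/s) and a Bateman biexponential impulse response
`h(t) ∝ exp(−t/τ2) − exp(−t/τ1)`, `0 < τ1 < τ2`, normalised to unit area.
Defaults τ = (0.75, 2.0) s; the kernel peaks `ln(τ2/τ1)·τ1τ2/(τ2−τ1)`
(≈1.2 s) after the impulse.

Processing order:

1. *Artifact correction.* Samples moving faster than 10 µS/s or outside
   [0.01, 60] µS are flagged and repaired by shape-preserving (PCHIP)
   interpolation between flanking clean samples. More than 50% flagged is a
   quality error: the participant is excluded, not repaired. Thresholds are
   declared defaults, not literature constants.
2. *Tonic baseline.* The 10th percentile of each 10 s bin (phasic responses
   decay within a few seconds, so a low percentile tracks the tonic floor),
   PCHIP-interpolated and lightly smoothed.
3. *Driver deconvolution.* Ridge-regularised frequency-domain inversion of
   `raw − SCL` against the kernel, ridge λ = 3·10⁻³ of the kernel's peak
   spectral power. λ trades inversion accuracy against noise amplification:
   at this value a clean forward-simulated SCR is recovered with < 10%
   relative rms error while the driver remains stable under sensor-scale
   noise. Negative driver mass is truncated into the residual, so
   `SCL + SCR + residual ≡ raw` holds exactly by construction.
4. *Per-participant impulse response.* (τ1, τ2) are fitted in two steps —
   coarse grid, then gradient-based refinement (L-BFGS-B on (τ1, τ2−τ1)) —
   minimising `w_neg·negativity + w_ind·indistinctness` of the deconvolved
   driver, with negativity = mean negative driver mass and indistinctness =
   1 − (fraction of positive driver mass in the top decile of samples).
   Weights default to (1, 1); both terms are declared operationalisations of
   the qualitative requirements that a correct kernel yields a non-negative,
   sharply concentrated driver. On synthetic data the fit recovers injected
   constants within ±20%.
5. *1 Hz aggregation and normalisation.* Per-second means of SCR and SCL,
   then z-scoring over the participant's whole session (n−1 divisor).
   Z-scoring removes sensor gain and basal-level differences, so
   between-participant correlations reflect shared dynamics; a zero-variance
   track returns zeros with a degenerate flag.

## SPC index and its null

SPC for a feature is the unweighted arithmetic mean over dyads of the
within-dyad Pearson correlation, computed over pairwise-complete seconds
(≥ 30 required). The null — observed compliance is a room-level
environmental confound, not dyad-specific coupling — is sampled by a
shuffled-pair bootstrap: each of 10 000 replicates draws, per room, as many
unordered random pairs of distinct co-located participants as the room has
real dyads and records the mean of their correlations. Pairs never span
rooms; within a replicate a participant appears in at most one drawn pair
(the draw is a random disjoint pairing, matching the number of observed
compliances), and draws are independent across replicates. The null sample
yields a percentile 95% CI and a one-tailed add-one p-value
`(1 + #{null ≥ observed}) / (1 + n)`, which cannot be zero. P-values are
Holm–Bonferroni-adjusted; the default family split corrects the windowed
HRV tests as one family and the fast 1 Hz signals (SCR, SCL, HR1) as
another.

*Forced-behaviour filtering.* Feature windows containing a task-change
instant (optionally also role-switch instants) can be removed before
correlation; the retained fraction is reported and a reliability warning is
issued below 20% retention, where the filtered estimate degenerates.

## Event-locked analysis

Run/test events (compiling/running code, executing assigned tests) are
pooled across kinds — the outcome (pass/fail), not the kind, carries the
valence. Per dyad, an event is retained iff it follows the previously
*retained* event by ≥ 10 s (the first of each dense cluster is kept); the
rule is idempotent and guarantees retained separation. Epochs are 21
samples of the z-scored SCR track, −10…+10 s inclusive around the event
second. Both dyad members are epoched at every retained event and
classified by their role at event time (drive/navigate) and the outcome.
Participants contribute one curve per condition — the mean of their own
epochs — and grand averages weight participants equally, so productive
dyads do not dominate. Participants with zero epochs in a condition are
absent, not zero-filled. Lagged-difference curves `d(t) = x(t) − x(t−10 s)`
are computed on the continuous track *before* epoching so the leading
window samples have context. Condition-difference curves (role: drive −
navigate; outcome: pass − fail) are formed per participant, excluding
participants lacking either condition; inference refuses fewer than three
paired participants.

## Minimum-width envelope (MWE) bands

A pointwise percentile band controls the error rate per time point only;
the chance that a whole curve exits it somewhere grows with the number of
effectively independent time points. The MWE is a simultaneous band:
starting from the pointwise min/max envelope of a training set of curves, a
greedy pass removes, k times, the curve whose removal most reduces total
envelope area (L1 over time; ties break to the lowest curve index; bounds
are always the min/max of survivors, no inflation). k is tuned on an
equal-size held-out validation split: the largest k whose envelope still
contains ≥ 95% of validation curves *entirely*. Bands are nested in k, so
coverage is non-increasing and the search stops at the first miss; if even
k = 0 under-covers, k = 0 is returned with a warning. The stepwise greedy
is optimal at k = 1 by construction and near-optimal at k = 2 (exact
agreement with exhaustive search on the large majority of small instances,
asserted in the suite); it is never below the optimum.

Two tests on per-participant difference curves:

* *Bootstrap-centred*: resample participants with replacement (10 000
  default), split the bootstrap mean curves, tune, and reject if zero exits
  the band at any time point. Centred on the observed difference.
* *Permutation-centred*: flip condition labels within participants
  (sign-flips of difference curves) to build a zero-centred null envelope;
  reject if the observed mean difference exits it. Exact by symmetry.

**Resolution requirement.** The envelope of an n-curve training split
leaves a fresh curve with escape probability ≈ 2·m_eff/n at k = 0, where
m_eff is the number of effectively independent time points. The tuning
construction therefore needs n ≫ m_eff/α. Event-locked SCR means are
smooth (m_eff ≈ 5 over the 21-sample grid); with 500-curve splits the k = 0
envelope's fresh-split coverage sits close to the 95% target, so the tuning
occasionally starts below target and says so (an under-coverage warning).
At the 5000-curve splits of a 10 000-sample bootstrap the construction has
ample slack.

**Known limitation — small-sample bootstrap.** With 20 participants the
percentile bootstrap of a mean is anti-conservative, and the any-time-point
union amplifies this: the bootstrap-centred test rejects a true null in
roughly twice the nominal α = 0.05 in the 20-participant calibration study,
while the inflation vanishes as the panel grows and the permutation-centred
variant (exact by sign-flip symmetry) stays at nominal level, as the test
suite's calibration checks show. For small panels the permutation variant is the
reliable default; the bootstrap variant is retained for its interpretable
observed-difference centring, and both are reported side by side in the
analysis drivers.

## Synthetic classroom generator

The generator emulates the study conditions end to end so every downstream
stage is testable with known ground truth. It writes the same CSV formats
the importers read.

* **Structure**: `n_rooms` rooms × `dyads_per_room` dyads × 2 participants;
  default 4 × 7 (the study's 28 dyads) over 1800 s sessions at desk scale.
* **Coupling model**: a smooth unit-variance latent arousal component per
  participant, mixed from room, dyad, and individual terms so the
  within-dyad correlation is `max(dyad_coupling, room_coupling)` and the
  within-room cross-dyad correlation is `room_coupling` (defaults 0.3 /
  0.1). The component modulates the log-IBI noise scale (carrying coupling
  into SDNN tracks) and the tonic EDA drift. The mixing model is a
  stand-in: no quantitative coupling model of the study population is
  claimed, only known, recoverable targets.
* **Cardiac**: lognormal IBIs around an 850 ms baseline drifting +6% over
  the session (heart rate declines from session start), base log-sd 0.05
  scaled by `exp(0.35·s(t))`. Beat times are generated vectorised, with
  slow components evaluated at approximate beat times (they vary over
  ~30 s, so the approximation is immaterial). Only beat times are
  generated — no ECG waveform morphology.
* **EDA**: tonic level (participant-specific base, slow random walk, latent
  drift) + driver impulses ⊛ Bateman kernel + Gaussian sensor noise
  (0.02 µS). Spontaneous SCRs at 3/min; each run/test event injects an
  impulse into both members with role×outcome-specific mass (defaults
  0.40–0.90 µS·s, failure > success and driver > navigator) at a 1–3 s
  post-event lag (driver 1.5 s, navigator 2.5 s).
* **Protocol**: 420 s role blocks with a self-paced uniform 2–20 s switch
  delay; run/test events per dyad from a homogeneous Poisson process
  (0.4/min, matching the study's ~36 events per dyad over 90 min) thinned
  to 1 s separation, placed away from session edges so epochs fit; pass
  probability 0.35 (successes are the rarer outcome).
* **Null classroom**: `dyad_coupling = 0` with `room_coupling` *retained*
  and response maps equalised — the null keeps the environmental confound
  the room-restricted bootstrap is designed to absorb, which is the
  stricter calibration.
* Fixed seed ⇒ bit-identical output.

What passing tests on this generator do *not* show: robustness to real
motion artifacts beyond the injected kinds, device clock drift,
non-stationary confounds (temperature, posture), or the true coupling
structure of human dyads. Calibration results transfer to real data only
insofar as the null model (exchangeable co-located participants) is
credible there.

## Calibration studies and problem sizes

Correctness is demonstrated by calibration and recovery at sizes chosen to
keep a full run in minutes on one core:

* envelope containment: 1000 bootstrap curves (500/500 split) from 20
  simulated participants;
* envelope null rejection: 1000 replicates × 20 participants × 1000
  bootstrap curves;
* SPC null CI coverage: 500 null classrooms (4 rooms × 7 dyads, 1800 s),
  2000 bootstrap draws each — under exchangeability the dyad mean should
  fall at or below the 95% CI upper bound in about 97.5% of replicates
  (a two-sided interval used one-sidedly), which the study reproduces;
* coupling recovery: measured dyad-mean SDNN60 correlation is monotone in
  injected coupling {0, 0.3, 0.6} (mildly attenuated by SDNN estimation
  noise); injected role-specific event responses reappear in the
  condition-difference grand mean at the injected lag plus the kernel rise
  time, within the 1 Hz grid.

## Numerical notes

* Envelope tie-breaks go to the lowest curve index; duplicated extreme
  values yield zero single-removal reduction via top-two bookkeeping, so
  bootstrap-duplicated curves are handled without special cases.
* Window start times are snapped to 9 decimals to keep `60·(1−1/3)`-style
  steps on clean second boundaries.
* Degenerate inputs: zero-variance tracks z-score to flagged zeros; dyads
  with degenerate tracks are excluded with a warning (error only if none
  remain); an all-zero EDA signal decomposes to all-zero components and
  returns default kernel constants with zero compound error.
* All randomness flows through `numpy.random.Generator` seeded per study;
  train/validation splits record their seed in output metadata.
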