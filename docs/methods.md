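# Methods

`dacue` analyzes trial-structured recordings from a primate Pavlovian
cue-value task: on each trial the animal fixates a central point (FP), a
conditioned stimulus (CS) appears at a jittered delay and signals either a
large reward (LR, delivered during the CS) or a small reward (SR, delivered
after CS offset), and the animal's anticipatory licking, midbrain dopamine
(DA) unit activity, and — in a separate control task — visually guided
saccade latencies are measured before and during pharmacological
inactivation of the superior colliculus.  Because no public dataset exists
for this design, the package pairs every analysis with a synthetic session
generator whose parameters are the ground truth the analyses are tested
against.

## Conventions

All times are seconds on a per-trial clock (trial start = 0); events are
stored absolutely and aligned on demand.  Every analysis window is
half-open `[t0, t1)`.  Milliseconds appear only in rendered reports.

## Synthetic sessions

A session is a control ("pre") block followed by an inactivation block
(default 60 + 60 trials, matching a typical ~60-trial control block in this
preparation).  Per trial: the value label is Bernoulli(1/2); the CS onset is
FP onset + Uniform[0.7, 1.2] s; CS duration defaults to 1.0 s and is
configurable (a second animal in this preparation used 1.7 s); the LR is
delivered 0.9 s after CS onset (inside the CS period) and the SR 0.3 s
after CS offset.

**Spikes** are an inhomogeneous Poisson process,

    lambda(t) = b + sum_k A_k(value, condition) * exp(-(t - c_k)^2 / (2 s_k^2)),

drawn exactly by thinning against `lambda_max = b + sum_k max(A_k, 0)` (no
time discretization).  Each event-locked Gaussian bump is parameterized by
its ground-truth onset; the center is `c_k = event + onset_k + 2 s_k` so the
bump rises from near zero at the bookkept onset.  Defaults emulate the
qualitative response pattern of putative DA neurons in this task:

| kernel | onset | sigma | A (LR) | A (SR) | rationale |
|---|---|---|---|---|---|
| FP | 85 ms | 15 ms | 20 sp/s | 20 sp/s | phasic trial-start response, value-blind (cue value still unknown) |
| CS | 85 ms | 15 ms | 25 sp/s | 7.5 sp/s | value-coded cue response; SR response "weak or absent" |
| RW | 100 ms | 15 ms | 0 | 0 | fully predicted rewards evoke no prediction-error response (overridable for unpredicted-reward screening) |

Baseline rate defaults to 5 spikes/s, the middle of the 1–10 Hz DA
screening range.  The CS onset of 85 ms and the LR amplitude of 5x baseline
match the operating point at which the latency detectors are exercised.
An `condition_scale_inactivation` factor (default 1.0 — the inactivation
left cue responses statistically unchanged in this preparation) scales all
amplitudes in the inactivation block.  Parameters whose conservative bound
`b + sum_k min(A_k, 0) < 0` are rejected before simulation.

**Licks** are Poisson at 0.5 /s baseline, elevated to 3.0 /s inside the
anticipatory window ([CS onset, reward) on LR trials, [CS offset, reward)
on SR trials).  The study reports licking only graphically, so these rates
are free parameters chosen for a clearly visible conditioned response at
session scale (a ~2 licks/s LR-SR difference over a 0.9 s window).

**Saccades** are Gaussian latencies (180 +/- 20 ms, truncated below 50 ms)
per target direction; during inactivation a +53 ms shift (the printed
prolongation) is applied to the affected direction (45 deg) only.

**Seeding.**  One master seed spawns `SeedSequence((seed, trial, component))`
substreams per trial and component (timing, spikes-per-neuron, licks), so
generation is reproducible and adding trials or neurons never perturbs
earlier draws.

What the generator deliberately omits: refractoriness, bursting, and
rate adaptation (spikes are exactly Poisson); lick-bout structure (licks
are timestamps, not detector bouts); eye traces; drug kinetics (the
inactivation is a step at the block boundary).  Passing tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to non-Poisson biology.

## Statistics

Small-sample tests are exact: the Wilcoxon signed-rank p-value is computed
by convolving the two-point distributions of the (doubled, hence integer)
midranks over all `2^n` sign assignments for n <= 25 (zeros dropped, ties
midranked), giving `p = 2*min(P(W+ <= w), P(W+ >= w))` capped at 1; above
n = 25 a tie-corrected normal approximation is used.  The two-sided sign
test is `min(1, 2*P(X <= min(n+, n-)))` with X ~ Binomial(n, 1/2).  A
direct consequence: with n uniformly positive differences the attainable
minimum is `2/2^n` — 0.00390625 at n = 9 and 0.015625 at n = 7, the exact
values printed for the cue-value licking discriminations at those sample
sizes.  Two-sample comparisons use Welch's t.  Permutation tests use the
difference of group means with the add-one rule `(1 + #{|T*| >= |T|}) /
(n_perm + 1)`; when there are at most 10,000 distinct relabelings they are
enumerated exhaustively and the p-value is exact.  The paired (sign-flip)
variant serves session-level pre-vs-inactivation comparisons.  No
multiple-comparison correction is applied anywhere, matching the analysis
style this mirrors.

## Behavioral analyses

The licking rate of a trial is the lick count in the cue-to-reward window
divided by its length (0.1 s bin counts are retained for time courses); a
fixed 0.7–1.3 s post-cue window is available as a variant.  Cue-value
discrimination is a paired Wilcoxon across units — sessions by default,
mirroring the N = 9 / N = 7 session-level design.  Within a session the
i-th LR trial is paired with the i-th SR trial in block order (deterministic
and unbiased; the source analysis does not state its pairing).  The
inactivation comparison is reported twice: per session (two-sample
permutation over trial-pair differences plus Wilcoxon over order-paired
block differences) and at the session level (paired Wilcoxon plus sign-flip
permutation across sessions), the latter being the default design.
Saccade prolongation is the per-direction difference of mean latencies with
a Welch t-test; directions are matched exactly since targets are discrete.

## Spike-train analyses

**SDF.**  The spike density function is a Gaussian-kernel rate estimate
(sigma 10 ms, truncated at +/-4 sigma, 1 ms grid, spikes assigned to the
nearest grid point), averaged over trials.  One spike contributes unit
mass, so the SDF integrates to the mean spike count per trial (edge
truncation aside) and a lone spike peaks at `1/(sigma*sqrt(2*pi))`.  The
smoothing width is configurable; latency results should be read jointly
with it.

**L latency** is the first grid time at or after cue onset where the
CS-aligned SDF of LR trials exceeds `baseline mean + 2 SD`, with mean and
SD taken across the grid points of the −500–0 ms baseline window of the
trial-averaged trace (an across-trial variant is available).  No minimum
supra-threshold duration is imposed (strict first crossing); a flat trace
returns no latency rather than zero.

**V latency** is the onset of sustained value differentiation.  Trials are
order-paired; single-trial rates are kernel-smoothed (sigma 5 ms); at each
evaluation point an exact two-sided sign test (alpha 0.05, ties dropped) is
applied to the paired LR−SR rate differences; V is the first point of the
earliest run of consecutive significant evaluations spanning strictly more
than 15 ms.  Two design choices here deserve justification because the
run-length rule is the detector's only false-positive control:

* *Evaluation spacing (10 ms, not the 1 ms rate grid).*  Smoothing makes
  adjacent 1-ms bins re-test the same spikes, so a single chance
  coincidence already spans a >15 ms significant run.  Under the generator
  null (LR and SR amplitudes equalized) the fine-grid rule detects a
  spurious onset in ~25% of sessions at alpha 0.05 — useless as a 5%-level
  control — largely independent of smoothing width (13% at sigma 5 ms,
  23% at sigma 20 ms).  Evaluating every 10 ms, so that consecutive tests
  are approximately decorrelated at sigma 5 ms, brings the measured null
  detection rate to 0.04–0.07 (600 null sessions), i.e. the familywise
  rate over the whole search window approximates the nominal level.
* *Narrower smoothing than the SDF (5 ms vs 10 ms).*  The kernel leaks
  evidence backwards by up to 4 sigma; at 10 ms a genuine differentiation
  could appear up to 40 ms before the true onset and hence before the L
  crossing.  At 5 ms the leak is bounded by 20 ms and the recovered
  ordering V >= L holds in ~92–95% of joint detections, as it must when
  the SR response is a nonnegative attenuation of the LR response.

With 60-trial blocks (~27 LR/SR pairs) the detector's power at the default
5x-baseline LR amplitude is ~0.25–0.35 per session with a median onset
error of ~10–20 ms; the detector trades sensitivity for calibrated
specificity.  Fewer than 6 pairs cannot reach two-sided significance at
alpha 0.05 and are reported as `undetectable` rather than "no onset".  The
search window defaults to [0, 0.5) s after cue onset — the phasic
cue-response epoch — and, like the spacing, smoothing, alpha, and
persistence, is a parameter.

**Window rates** are spike counts divided by window length in the
event-aligned default windows 100–300 ms (FP, CS) and 150–350 ms (reward).
Per-neuron block comparisons use Welch's t plus a permutation test; the
population comparison is a paired Wilcoxon across neurons' mean rates
(requiring at least 5 neurons for a meaningful exact test).

**Screening** classifies a unit as putative DA by conjunction: location in
SNc/VTA, a phasic response to unpredicted reward, baseline rate in
[1.0, 10.0] Hz, and spike width exceeding 1.5x the median width of nearby
fast-firing (>40 Hz) SNr reference units; an empty reference set leaves the
width criterion indeterminate and rejects conservatively.

## Numerical and degenerate-input choices

Exact-test p-values are computed in double precision from integer counts;
the signed-rank convolution uses doubled midranks to stay integral.
Identical groups short-circuit Welch's t to (0, 1); zero-variance unequal
groups raise.  Permutation comparisons use a `1e-12` slack when counting
`|T*| >= |T|` to make exhaustive enumeration robust to float noise.
Latencies are reported at grid resolution (1 ms for L, the evaluation
spacing for V) and rounded to ms only in rendered reports; absent onsets
are rendered as "none", never 0.

## Problem sizes used in the test suite

Calibration and recovery tests run at the block sizes the design dictates
(60-trial control blocks, 9-session experiments): 400 null datasets for
permutation calibration, 200 generator-null sessions for the
differentiation detector, 300 sessions across onsets {70, 85, 100} ms for
latency recovery, and 200 nine-session experiments for the end-to-end
behavioral check.  These sizes give binomial standard errors of ~1.5
percentage points on a 5% rate while keeping the full suite under a
minute of compute.

## Known limitations

* The V detector's power at realistic trial counts is modest by
  construction; population-level pooling across neurons (as a figure-level
  analysis would do) is out of scope here.
* The L rule inherits the noise of the trial-averaged SDF: with few trials
  it can cross early during baseline fluctuations, which is visible in
  small-block analyses.
* Exactness claims for the Wilcoxon stop at n = 25; beyond that the normal
  approximation with tie correction is standard but approximate.
* The generator's Poisson assumption makes variance equal to the mean;
  real DA spike trains are often under- or over-dispersed, which would
  change detector calibration.
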