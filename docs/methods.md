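# Methods

This note documents the models, estimators and numerical choices behind
`qeegrecovery`, and what the synthetic validation does and does not show.

## 1. The measurement model

All pattern decisions are made on an **amplitude envelope**: the half
peak-to-peak amplitude of the filtered signal in 0.5-s windows with a 0.25-s
hop, computed per channel and combined across the two channels by the
per-window **minimum**. The minimum implements "above threshold in both
channels" as a single comparison; it is deliberately conservative (a burst
visible in only one channel does not count).

Filtering is a 4th-order Butterworth band-pass (0.3–100 Hz) applied
forward–backward (zero phase) followed by a second-order IIR notch at 50 Hz
with quality 30. The realization matters only at the edges of the band: the
suite asserts ≥ 20 dB attenuation at 50 Hz and ≤ 5% RMS change at 10 Hz, and
passband idempotence to 1%.

**Burst detection.** Bursts are maximal runs of combined envelope above
10 μV; suppression gaps shorter than 0.5 s (the minimum inter-burst
suppression in the annotation rules) are merged into the surrounding burst,
and events shorter than 0.1 s are dropped. Because a 0.5-s peak-to-peak
window is elevated whenever it *overlaps* a burst, raw run lengths
overestimate burst time by roughly (window − hop) per event; event
boundaries are therefore placed at half-hop midpoints with the window length
subtracted (runs touching the trace edge extend to the edge). This makes
total burst time an approximately unbiased estimate of true
envelope-above-threshold time, which both the BSR and the planted-truth
validation rely on.

**Pattern classification.** Rolling 60-s windows (hop 10 s) of the combined
envelope are labeled:

* *continuous* — window max > 10 μV and an essentially unbroken floor above
  5 μV (at most ~1% of valid envelope samples below 5 μV). A percentile-style
  floor rule is too loose here: with suppressions as short as 0.5–0.8 s, the
  sub-5 μV evidence for burst suppression occupies only a few percent of a
  window, and a 5%-quantile rule misclassifies late burst suppression as
  continuous.
* *isoelectric* — no sample above 10 μV and a sub-5 μV run of at least 30 s.
* *burst suppression* — at least one burst present.
* windows with intermediate amplitude and no bursts fall back on the window
  median (below 5 μV → isoelectric, else burst suppression); windows
  dominated by artifact inherit the neighbouring label.

Adjacent same-label windows are merged; the 10-s hop sets the native onset
resolution. Two boundaries are refined past the grid because the study's
features are defined by them: the first burst-suppression onset snaps to the
first detected burst, and the first continuous onset snaps to the last
sub-5 μV envelope sample before the continuous run. OTOB is the start of the
first burst-suppression interval (or of the first continuous interval if
burst suppression is never seen); TTNT is the start of the first continuous
interval, right-censored at the monitoring horizon (240 min).

**Artifacts.** Envelope samples above 300 μV — an order of magnitude beyond
any physiological burst here — are masked, together with a 3-s guard on each
side covering the band-pass ringing of large transients, from both burst
detection and window statistics. Scheduled one-minute segments containing
samples beyond ±1000 μV or a ≥ 1-s exact flatline may slide by up to ±60 s
(nearest position first) to find a clean minute, else they are flagged and
carry no feature values.

**Features.** Per segment: BSR = total burst time / 60 s (∈ [0, 1], higher =
more cortical activity); WPE = variance-weighted permutation entropy with
embedding m = 5, delay τ = 1 (the common default for kHz-range biosignals;
a 60-s segment provides ≥ 15 000 vectors even at 250 Hz), ties in ranks
broken by index order, channels averaged, constant segments defined as 0.
TWA is the trapezoidal integral over the post-ROSC schedule {5, 30, …, 240}
min divided by the spanned duration; flagged segments are dropped first, and
the pre-arrest baseline minute is summarized separately, not integrated.

**Statistics.** Group comparison gates on a Lilliefors-corrected
Kolmogorov–Smirnov normality test per arm (the KS-with-estimated-parameters
most statistics packages apply) and an F-ratio variance test at α = 0.05;
Student's t is used only if both pass, otherwise the two-sided rank-sum
test. Spearman CIs use Fisher's z with SE 1/√(n−3). AUC is the Mann–Whitney
pair statistic with half-credit for ties, scores oriented so higher = higher
death risk (onset times as-is, TWA features reversed), with a seeded
stratified bootstrap CI (2000 resamples). Kaplan–Meier curves come from the
product-limit estimator; the median is the first time S(t) ≤ 0.5. No
multiple-testing correction is applied; each feature is reported marginally.

## 2. The synthetic cohort generator

The generator emulates a two-arm study (treated "H2" vs control "Ctrl",
20 animals per arm) over 4 h post-ROSC at a nominal 1000 Hz (a 250 Hz
desk-scale mode is the default for tests; all thresholds are amplitude-based
and rate-independent).

**Planted recovery times.** OTOB and TTNT are drawn from distributions
fitted exactly to each arm's published quartile triple: a shifted log-normal
for right-skewed triples, its reflection for left-skewed ones (the H2 OTOB
triple is left-skewed), a normal for symmetric ones. Draws are stratified
(one inverse-CDF draw per probability stratum, jittered within stratum) and
rank-coupled through a latent per-animal severity, so that a 20-animal
cohort's quantiles reproduce the fitted distribution and slow burst onset,
slow normalisation, low burst occupancy, death, high NDS and high S100B
co-occur. TTNT draws beyond the 240-min window yield animals that remain in
burst suppression at 4 h (censored TTNT), as a minority of animals do.

**Burst-occupancy trajectory.** Each animal's instantaneous burst occupancy
is 0 before OTOB, jumps to a floor of 0.10 at OTOB (bursts appear abruptly;
without the floor, near-zero early occupancy would make the onset
undetectable within a window), ramps linearly over 45 min to a per-animal
plateau, and is capped at 0.79 during burst suppression (bursts ≤ 3 s with
suppressions ≥ 0.8 s cannot exceed 3/3.8) and 0.95 in the continuous phase.
The plateau is solved per animal (bisection) so that the trajectory's
trapezoidal TWA — evaluated exactly as the measurement pipeline evaluates
it — equals a target drawn from the arm's published Normal TWA-BSR
distribution; targets beyond the achievable range are clamped to it.

**Waveforms.** Activity is band-limited Gaussian noise per event.
Isoelectric background and suppressions scale to a target standard deviation
(envelopes ≈ 3–4 μV, safely under the 5 μV rule). Bursts and continuous
high runs scale so that the *minimum* rolling 0.5-s half peak-to-peak equals
a drawn amplitude (12–22 μV), i.e. every envelope sample inside the event
clears 10 μV; continuous low runs are flattened to a ceiling of 8–9.5 μV so
the continuous floor never dips below 5 μV. Burst/suppression (and
high/low) cycle lengths are chosen so each cycle realizes the trajectory's
occupancy exactly under the duration constraints. Since a carrier needs a
fraction of a cycle to build peak-to-peak amplitude, rendered bursts are
extended by 0.075 s + 0.0625·exp(−(b−0.6)/0.6) per edge, calibrated once
against controlled flat-occupancy sweeps at 250 and 1000 Hz so that measured
envelope-above-threshold time matches the planted duration (residual
occupancy error ≲ 0.02). The planted complexity index rises with occupancy
and widens the carrier band (≈ 12–42 Hz upper edge), so measured WPE
increases through recovery; WPE levels are not calibrated to any published
value. A 50 Hz sinusoid (2 μV) is added to both channels, plus ~1/h
high-amplitude (2000 μV) transients as artifacts. Every event carries its
own seed, so regeneration is bit-identical and independent of chunking.

**Outcomes.** Death counts are fixed at n − round(n·survival probability)
(18/20 survive in H2, 8/20 in Ctrl) and assigned to the worst-ranked animals
by noisy severity; death times come from a log-normal fitted so the
cohort's Kaplan–Meier quartiles match the published control values (the
published median survival is read as a KM median). For arms whose printed
quartiles are entirely censored (H2: 96 [96–96]) the fit is unidentifiable
and a generic post-arrest spread (log-normal, median 25 h) is used for the
few deaths. NDS (0–500, 500 from death onward) and serum S100B (arbitrary
units, rising after resuscitation) are noisy monotone functions of the same
latent severity; their rank correlations with the EEG features emerge in the
published direction and rough magnitude but are not separately calibrated.

## 3. What the synthetic validation shows — and does not

Passing tests show that the *pipeline* recovers what was planted: onset
medians within the acceptance tolerances, measured TWA-BSR within ~0.01 of
the planted group means, ≥ 95% of animals within 0.5 min (OTOB) / 2 min
(TTNT) of truth. They do not validate the biology: real post-arrest EEG has
non-stationary amplitude drift, electrode artifacts richer than spikes and
flatlines, seizures and epileptiform transients (out of scope here), and
annotation ambiguity between human readers. The generator's amplitude
margins are deliberately clear of the 5/10 μV rules; a recording hovering
at a threshold would classify less stably than anything tested here.

## 4. Problem sizes and determinism

Default validation scale: 20 + 20 animals, 4-h recordings at 250 Hz
(two channels, ~3.6 M samples each), chosen as the point where cohort
medians are meaningful yet a full run stays in the minutes range; the
acceptance script and the cohort-level tests both use it. All randomness
flows from one master seed through per-group, per-animal and per-event
seed streams; repeated runs produce byte-identical CSVs, which the suite
asserts via checksums.

## 5. Known limitations

* The classifier is single-deterministic; inter-rater disagreement in
  visual annotation has no analogue here.
* The 10-s classification hop bounds onset resolution away from the refined
  boundaries; refinement is only applied to the two onsets that define
  features.
* EDF I/O is not provided; recordings interchange as plain-text matrices
  with an `fs=` header (see `qeegrecovery.io`).
* Group-restricted AUCs in a nearly one-class arm (2 deaths of 20) are
  computed but flagged with a small-sample warning; their bootstrap CIs are
  unstable by nature.
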