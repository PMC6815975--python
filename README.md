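# qeegrecovery

Quantitative EEG analysis of early recovery after cardiac arrest, built
around a fully synthetic, ground-truth-planted cohort.

After restoration of spontaneous circulation (ROSC), cortical activity
recovers through a stereotyped sequence — isoelectric silence, then burst
suppression, then a continuous background — and how fast an individual moves
through it is strongly prognostic. This package implements the quantitative
version of that analysis for two-channel rodent EEG:

* **Pattern timeline** — amplitude-envelope classification of the recording
  into `isoelectric` / `burst_suppression` / `continuous` intervals, using
  the standard amplitude rules (no activity above 5 μV for ≥ 30 s is
  isoelectric; bursts exceed 10 μV in both channels with ≥ 0.5 s low-amplitude
  suppressions between them; a continuous trace keeps its minimum above 5 μV
  with peaks above 10 μV).
* **Onset features** — OTOB (onset time of burst: minutes from ROSC to the
  first burst-suppression pattern) and TTNT (time to normal trace: minutes
  from ROSC to the first continuous pattern, right-censored at the end of
  monitoring).
* **Per-segment features** — on one-minute segments taken at 5 min post-ROSC
  and every 30 min thereafter (band-passed 0.3–100 Hz, 50 Hz notch):
  the burst-suppression ratio BSR = (time occupied by bursts)/(segment
  length), oriented so *higher = more activity = better*, and the normalized
  weighted-permutation entropy
  `WPE = −Σ p_w(π) ln p_w(π) / ln(m!)`, where ordinal patterns π of
  delay-embedded vectors are weighted by each vector's variance (m = 5,
  τ = 1).
* **Time-weighted averages** — TWA-BSR and TWA-WPE: trapezoidal integral of
  the per-segment values over the 4-h observation window divided by its
  span, the standard construction for cumulative exposures.
* **Outcome statistics** — normality-gated two-group comparison (Lilliefors
  gate, Student's *t* or rank-sum), Spearman correlation with Fisher-z CI,
  ROC/AUC for 96-h survival with a stratified bootstrap CI, and Kaplan–Meier
  curves with a log-rank test.

Because real post-arrest recordings are rarely shareable, the package ships
a first-class synthetic cohort generator (`qeegrecovery.synthgen`): each
simulated animal carries a *planted* phase timeline, burst-occupancy
trajectory and outcome variables, so every detector and statistic in the
pipeline can be validated against known truth.

## Worked example

Simulate and analyze a small two-arm cohort (five animals per arm, 4-h
recordings at the reduced 250 Hz desk rate):

```bash
qeegrecovery run-all --seed 1 --fs 250 --n-per-group 5 --quiet --out demo_out
```

which prints (abridged):

```
# qeegrecovery report  seed=1 config_hash=53133a63ff8f
animals: 10

[Ctrl] n=5  OTOB median 25.32 min, TTNT median 213.28 min (1 censored), TWA-BSR 0.535 +/- 0.147, TWA-WPE 0.466 +/- 0.040
[H2] n=5  OTOB median 22.27 min, TTNT median 170.02 min (1 censored), TWA-BSR 0.663 +/- 0.083, TWA-WPE 0.502 +/- 0.018

group_compare[t]             twa_bsr                   1.693  p=0.1288
spearman                     twa_bsr~s100b_240        -0.939 [-0.986, -0.758]  p=5.484e-05
roc_auc                      otob_min                  0.875 [0.583, 1.000]  p=0.06911
km_median                    survival[Ctrl]           95.500  p=0.2051
```

Reading it: the treated (H2) arm starts bursting ~3 min earlier and reaches
a continuous trace ~40 min earlier than controls, and carries a higher
TWA-BSR; slower recoverers have higher serum S100B (Spearman −0.94 for
TWA-BSR, i.e. less burst activity ↔ more brain injury), and burst-onset time
discriminates 96-h survival (AUC 0.88). At n = 5 per arm the group
comparisons are underpowered — p-values sharpen at the study size (n = 20).

The same stages are available as a library:

```python
from qeegrecovery import (GeneratorConfig, generate_cohort,
                          generate_recording, PipelineConfig,
                          analyze_recording)

cfg = GeneratorConfig(n_per_group=20, fs=250.0, seed=1)
profiles = generate_cohort(cfg)
rec = generate_recording(profiles[0], cfg)           # two channels, μV
res = analyze_recording(rec, PipelineConfig(generator=cfg, seed=1))
print(res.otob_min, res.ttnt_min, res.twa_bsr)       # vs profiles[0] truth
```

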