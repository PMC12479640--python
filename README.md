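# swallowsound

Acoustic and perceptual profiling of swallowing sounds recorded by
**cervical auscultation** (a microphone on the neck during feeding), aimed
at clinicians and researchers characterising feeding in preterm neonates.
Reference recordings of this population cannot generally be shared, so the
package pairs every analysis stage with a synthetic-data generator whose
ground truth is analytic, making the whole pipeline testable end to end.

## What it computes

**Per-swallow acoustic features** from a 16-bit PCM recording (44.1 kHz
study standard) and a human-annotated swallow interval table:

- *duration* — annotated `end − start` in seconds;
- *peak frequency* — the signal is high-pass filtered (4th-order
  Butterworth, 400 Hz cutoff), framed into 20 ms windows with 50% overlap,
  and the maximum-energy frame's Welch PSD (10 Hann sub-frames, 50%
  overlap) is normalised; the peak frequency is the smallest grid frequency
  `f` whose cumulative power satisfies `Σ_{f'≤f} PSD(f') ≥ 0.95`;
- *peak amplitude* — `20·log10(max|x|)` in dB re 1 LSB (16-bit full scale
  = 90.31 dB);
- *peak power* — clipped samples are removed (shortening the effective
  duration), and the largest per-frame mean-square power
  `10·log10(Σx²/n)` is reported in dB re 1 LSB².

**Perceptual rating schema** — a closed inventory of 9 pre-swallow breath
sounds, 7 during-swallow sounds (the IDS–BTS–FDS–GRS sequence plus
crisp/quick/loud descriptors) and 9 post-swallow breath sounds, rated
yes / no / cannot_be_determined per neonate, with a strict `> 80%`
consistency rule, two-rater consensus merging, and a rule classifier:
a swallow pattern is *uncoordinated* if a bolus transit sound occurs
without post-swallow normal breathing, or a glottal release sound is
accompanied by an adventitious post-swallow sound (wet breathing, rattly
chest, cough, wheeze, crackles, throat clearing, stridor); otherwise it is
*coordinated*.

**Agreement statistics** — percent agreement `po`, Cohen's
`κ = (po − pe)/(1 − pe)`, and the prevalence-adjusted bias-adjusted kappa
`PABAK = (k·po − 1)/(k − 1)`, with qualitative bands (≥ 0.80 excellent,
0.61–0.80 substantial, 0.41–0.61 moderate, 0.21–0.41 fair, below 0.21
slight to poor).

**Cohort statistics** — mean/SD/IQR summaries, a Shapiro–Wilk normality
gate, Pearson correlation with Fisher-z confidence intervals
`tanh(atanh r ± z/√(n−3))`, Spearman rank correlation, and the
correlation-based sample-size plan
`n = ⌈((z_{1−α/2} + z_{power})/atanh ρ)² + 3⌉`.

## Worked example

```sh
python examples/04_cohort_statistics.py
```

```
duration_s           mean     0.87  sd    0.28  n 80
peak_frequency_hz    mean  1762.96  sd  395.60  n 80
peak_amplitude_db    mean    89.54  sd    1.08  n 80
peak_power_db        mean    80.34  sd    5.52  n 80

Shapiro-Wilk on peak amplitude: W=0.986, p=0.564, normal=True
amplitude ~ comorbidities: r=0.29, 95% CI (0.08, 0.48)

planned cohort size to detect |r| >= 0.31 at 80% power: 80
```

The first block summarises the four acoustic parameters over a synthetic
80-neonate cohort generated at the published set-points (0.85 s, 1678 Hz,
89.67 dB, 80.83 dB). The Shapiro–Wilk line gates the choice of parametric
inference; the correlation line estimates the coupling between comorbidity
burden and swallow loudness that the generator injects at r = 0.24 (one
n = 80 draw lands at 0.29 here); the final line reproduces the power
calculation that motivates an 80-neonate cohort.

The other examples cover feature extraction from a simulated 2-minute
feeding session (`01`), consensus rating and coordination classification
(`02`), and inter-rater agreement, including the kappa-paradox cases where
κ collapses under skewed prevalence while PABAK tracks raw agreement
(`03`).

A thin CLI mirrors the library: `swallowsound simulate | extract-features |
rate-summary | agreement | cohort` (see `swallowsound --help`).

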