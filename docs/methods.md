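# Methods

## Signal model and acoustic features

The analysis operates on single-channel integer PCM audio (defaults:
44,100 Hz, 16-bit) with swallow boundaries supplied by a human-annotated
interval table. Automatic swallow detection is out of scope: boundary
identification in this field is done by trained raters from synchronized
audio, video and spectrogram views, and the package deliberately consumes
their output rather than emulating it.

Samples are kept in quantization units (LSB) end to end, and both decibel
features use 1 LSB as the 0 dB reference. This choice is an inference, not
a convention the data dictates: the 16-bit ceiling 20·log10(32767) =
90.31 dB tightly bounds the published cohort's mean peak amplitude
(89.67 dB), and no other common reference (dBFS, dB SPL) reproduces that
scale. The bit depth is configurable for recordings made at other depths.

Per annotated swallow:

- **Duration** is the annotated interval length. Segment cutting uses
  half-open sample windows `[round(start·fs), round(end·fs))` with
  round-half-up, so adjacent annotations tile a session exactly.
- **High-pass filter**: 4th-order Butterworth, 400 Hz cutoff, applied
  causally (forward only) — the plain reading of a "fourth-order" filter.
  A zero-phase forward–backward variant is available behind
  `FilterSpec(zero_phase=True)` and documented as having an 8th-order
  magnitude response. The filter removes feeding/handling energy below
  400 Hz that would otherwise dominate the power percentile.
- **Framing**: 20 ms frames, 50% overlap, trailing partial frame dropped.
  Segments shorter than one frame are rejected as unanalyzable rather than
  zero-padded, because padding biases power downward.
- **Welch PSD**: each frame is split into 10 half-overlapping Hann-windowed
  sub-frames whose length `⌊2L/11⌋` makes them tile the frame exactly;
  modified periodograms are averaged (scipy.signal.welch, detrending off)
  and the one-sided PSD is normalized to unit sum. An all-zero frame
  returns a zero-energy-flagged estimate; no uniform spectrum is
  substituted.
- **Peak frequency**: the per-frame energies select the maximum-energy
  frame; its normalized PSD is cumulated from low to high frequency and
  the smallest grid frequency reaching 0.95 is reported. The estimate is
  scale-invariant and quantized to the Welch grid (275.6 Hz at the default
  rates — tone-recovery tests therefore use a two-bin tolerance). Whether
  the original analysis pooled PSDs across frames or used the max-energy
  frame alone is not determinable; both are implemented
  (`mode="pooled"` / `"per_frame_max"`), max-energy frame is the default.
- **Peak amplitude**: `20·log10(max|x|)` on the raw, unfiltered segment
  ("the maximum signal value found in the swallow"); filtering first is
  available but non-default, since the filter can only reduce an extreme
  sample.
- **Peak power**: clipped samples (|x| ≥ threshold, default full scale)
  are removed from the sample stream and the effective duration shrinks
  accordingly; the censored stream is filtered, framed, and the maximum
  per-frame mean square is reported as `10·log10(max_f Σx²/n)`. Removal
  *before* filtering is a deliberate design choice: censoring after
  filtering lets clipped-sample energy smear into neighbouring samples
  through the IIR response, and the clip-invariance property (censored
  estimate within 0.1 dB of the clip-free construction) then fails.
  Mean-square power (energy divided by effective duration, both per unit
  sample time) keeps the dB re 1 LSB² scale on which a frame's power can
  never exceed the squared peak amplitude.

A feature that cannot be computed propagates as NaN with a reason code in
`AcousticProfile.reasons`; cohort summaries use available-case
denominators.

## Perceptual schema and the coordination rule

The parameter inventory (9 pre-swallow breath sounds, 7 during-swallow
sounds, 9 post-swallow breath sounds) is closed; unknown names are
rejected. File-level presence means "demonstrated on at least one
swallow"; the consistency flag requires strictly more than 80% of swallows
(the 0.80 boundary is excluded, matching the "> 80%" definition).

The coordination classifier treats the published definition's "and/or" as
two independent sufficient conditions for *uncoordinated*: (i) bolus
transit sound present and post-swallow normal breathing absent; (ii)
glottal release sound present together with at least one adventitious
post-swallow sound (wet breathing, rattly chest, cough, wheeze, crackles,
throat clearing, stridor — grunting, read as breath effort rather than
airway residue, is excluded). *Coordinated* requires a bolus transit sound
plus either post-swallow normal breathing or identical pre/post
breath-sound vectors. Uncoordinated takes precedence when rules overlap
(the clinically conservative choice); a consequence worth stating plainly
is that the "no change pre/post" branch can never rescue a profile that
already lacks post-swallow normal breathing. Ratings of
cannot_be_determined propagate as unknowns through three-valued (Kleene)
logic, and a rule that cannot be decided yields *undetermined* rather than
a guess. The classifier is exhaustively enumerated in the tests over the
post-swallow hypercube to confirm totality and precedence.

Consensus merging passes agreeing ratings through and requires an explicit
resolution for every disagreement, erroring with the offending parameter
names otherwise — silent tie-breaking would fabricate clinical data.

Cohort presence percentages use available-case denominators (neonates
rated cannot_be_determined are excluded per parameter) and half-up
rounding to one decimal, reproducing the convention of published cohort
tables (e.g. 62/79 → 78.5%, 15/80 → 18.8%).

## Agreement statistics

Cohen's κ returns NaN (flagged degenerate) when both raters are constant,
rather than an arbitrary 0 or 1. PABAK is reported alongside κ because
per-parameter prevalence in this domain is extremely skewed (several
parameters are present in ~0% or 100% of neonates), which collapses κ
while raw agreement stays high. The printed interpretation bands overlap
at 0.80 and leave (0.20, 0.21) unassigned; the implementation repairs them
to a total partition by assigning each edge upward: ≥ 0.80 excellent,
[0.61, 0.80) substantial, [0.41, 0.61) moderate, [0.21, 0.41) fair,
< 0.21 slight to poor. Pairs where either rating is cannot_be_determined
are dropped before tabulation. The headline band reported per parameter
follows PABAK.

## Cohort statistics

Summaries use the n−1 sample SD and linear-interpolation (type-7)
quantiles for the IQR — published IQRs cannot adjudicate the quantile
convention, so the most common default is used and documented. The
Shapiro–Wilk gate delegates to scipy (the test is used only as a
normality gate, not re-derived). Pearson intervals use the Fisher-z
transform; at r = 0.24, n = 80 the closed form gives (0.021, 0.437),
slightly narrower than the published (0.03, 0.45) — the original CI
method is unknown, and no attempt is made to force agreement. The
sample-size routine interprets the planned "difference ≥ 0.31" as a
correlation effect size, because the Fisher-z formula
`n = ⌈((z_{1−α/2}+z_{power})/atanh ρ)² + 3⌉` then reproduces the planned
n = 80 exactly; this reading is an assumption and is recorded as such.

## Synthetic data: what it emulates and what it does not

The audio generator renders swallows as sums of fixed-frequency tones with
random phase over Gaussian background noise, scaled so the largest sample
hits the requested amplitude exactly before quantization; sessions place
disjoint bursts (durations ~N(0.85, 0.31) s, tone frequencies
~N(1678.3, 413.5) Hz, amplitudes near 30,000 LSB ≈ 89.5 dB) at
Dirichlet-distributed gaps across 120 s. Optional clipping forces a
random sample fraction to full scale. Ground truth (95%-power tonal
frequency, exact peak amplitude, loudest-window mean square) is emitted
with every signal. The model deliberately omits the broadband, transient
character of real swallow sounds, suck–swallow–breath rhythm and room
acoustics: passing tests demonstrate correctness of the measurement
pipeline on signals with known spectra, not clinical validity on real
recordings.

The cohort generator draws comorbidity counts from a Poisson margin
(λ = 2.4, the sum of the published cohort's condition prevalences) and
per-neonate mean peak amplitude from N(89.67, 1.1), coupled by a Gaussian
copula. The latent correlation is inflated by the inverse of the
discrete-margin attenuation factor `corr(F⁻¹(Φ(Z)), Z)` (computed by
quadrature, ≈ 0.967 at λ = 2.4) so the *linear* correlation matches the
target r = 0.24; recovery simulations across 1,000 cohorts of n = 80 show
mean bias below 0.02. Perceptual ratings are drawn independently per
parameter at configurable prevalences (defaults: the published cohort
rates), and coordination labels are always produced by running the rule
classifier on the generated ratings, never sampled directly. Under
independent sampling at those prevalences the classifier labels most
synthetic neonates uncoordinated — an honest consequence of combining the
permissive rule with marginal prevalence rates (glottal release sounds in
100% of neonates and adventitious post-swallow sounds in ~70%), and a
caution against reading the generator's coordination rate as a cohort
estimate.

The two-rater generator makes rater B copy rater A with the configured
agreement probability, independently per parameter, which reproduces
PABAK = 2·agreement − 1 in expectation and the PABAK > κ ordering under
prevalence skew.

## Numerical choices and problem sizes

Filter design and filtering use second-order sections for stability.
The CDF threshold comparison uses `searchsorted` with a 1e-12 slack so a
cumulative sum that is exactly 0.95 up to roundoff still crosses. Percent
rounding uses decimal half-up (banker's rounding would turn 18.75 into
18.7). Statistical property tests run at deliberately modest sizes chosen
for tight-but-fast checks — 1,000 cohorts of n = 80 for correlation
recovery, 2,000 replicates for interval coverage, 100 replicates for the
Shapiro–Wilk gate — with seeded generators throughout.

## Known limitations

- The peak-frequency estimate is quantized to the Welch grid; at 44.1 kHz
  and 20 ms frames the resolution is ~276 Hz, coarse relative to the
  published cohort SD (413.5 Hz).
- The dB reference (1 LSB) and the correlation reading of the sample-size
  plan are inferences; both are flagged above.
- Consensus requires explicit resolutions and cannot model the discussion
  process that produced them.
- The synthetic audio model is spectrally stationary within a burst; it
  cannot test detection of the IDS–BTS–FDS–GRS fine structure, which is a
  human-rater construct here.
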