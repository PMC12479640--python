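"""Synthetic fixtures with analytic ground truth.

Real cervical-auscultation recordings of preterm feeding are rarely
shareable, so every pipeline stage is exercised on synthetic material
instead: tonal swallow bursts embedded in
white background noise (audio), two-rater nominal rating tables with
controllable prevalence and agreement, and cohort covariate tables with a
controllable comorbidity-loudness correlation.  The generators' default
set-points are the cohort's published operating conditions (0.85 s mean
swallow duration, ~1678 Hz peak frequency, ~89.7 dB peak amplitude, 2-min
sessions, r = 0.24); the tonal-burst model keeps ground truth analytic —
physiological realism is a non-goal.

Every generator is deterministic for a fixed seed; independent artifacts
draw from named substreams of one seed sequence so they can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .audio_io import AudioSignal
from .perceptual import (
    BREATH_SOUNDS,
    SWALLOW_SOUNDS,
    PARAMETER_INVENTORY,
    PerceptualProfile,
    Phase,
    Rating,
    RatingValue,
    classify_coordination,
    presence_from_swallows,
)

__all__ = [
    "SwallowSoundSpec",
    "CohortSpec",
    "TABLE3_PREVALENCE",
    "generate_swallow_audio",
    "generate_feeding_session",
    "generate_rating_pair",
    "generate_cohort",
]

# Published per-neonate presence rates used as default prevalences
# (pre- and post-swallow breath sounds; during-swallow descriptors).
TABLE3_PREVALENCE: dict[tuple[str, str], float] = {
    ("pre", "normal_breathing"): 62 / 79,
    ("pre", "wet_breathing"): 0.175,
    ("pre", "rattly_chest"): 0.0,
    ("pre", "grunting"): 0.15,
    ("pre", "crackles"): 0.0,
    ("pre", "stridor"): 0.325,
    ("pre", "wheeze"): 0.20,
    ("pre", "throat_clearing"): 0.0,
    ("pre", "coughing"): 0.0,
    ("during", "crisp_clear"): 0.95,
    ("during", "quick"): 1.0,
    ("during", "loud"): 0.888,
    ("during", "initial_discrete_sound"): 0.988,
    ("during", "bolus_transit_sound"): 1.0,
    ("during", "final_discrete_sound"): 0.988,
    ("during", "glottal_release_sound"): 1.0,
    ("post", "normal_breathing"): 0.563,
    ("post", "wet_breathing"): 0.20,
    ("post", "rattly_chest"): 0.0,
    ("post", "grunting"): 0.088,
    ("post", "crackles"): 0.0,
    ("post", "stridor"): 0.413,
    ("post", "wheeze"): 0.30,
    ("post", "throat_clearing"): 0.063,
    ("post", "coughing"): 0.013,
}


@dataclass(frozen=True)
class SwallowSoundSpec:
    """One synthetic swallow burst: tones + white noise, known ground truth.

    ``tones`` is a list of (frequency Hz, relative power) with total
    relative power <= 1; ``amplitude_lsb`` sets the exact peak sample value;
    ``noise_db`` is the background RMS in dB re 1 LSB (None = silent
    background); ``clip_fraction`` forces that fraction of samples to full
    scale to emulate recorder saturation.
    """

    duration_s: float = 0.85
    sample_rate: int = 44_100
    tones: tuple[tuple[float, float], ...] = ((1678.3, 1.0),)
    amplitude_lsb: int = 30_000
    noise_db: float | None = 40.0
    clip_fraction: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.tones)
        if total > 1 + 1e-9:
            raise ValueError(f"total relative tone power {total} exceeds 1")
        nyquist = self.sample_rate / 2
        if any(not 0 < f < nyquist for f, _ in self.tones):
            raise ValueError("tone frequencies must lie in (0, fs/2)")
        if not 0 <= self.clip_fraction < 1:
            raise ValueError("clip_fraction must be in [0, 1)")


def _true_peak_frequency(
    tones: tuple[tuple[float, float], ...], threshold: float = 0.95
) -> float:
    """Frequency below which >= threshold of the tonal power lies."""
    ordered = sorted(tones)
    total = sum(p for _, p in ordered)
    acc = 0.0
    for f, p in ordered:
        acc += p
        if acc >= threshold * total - 1e-12:
            return f
    return ordered[-1][0]


def generate_swallow_audio(
    spec: SwallowSoundSpec,
) -> tuple[AudioSignal, dict]:
    """Render one swallow burst; returns the signal and its ground truth.

    The float waveform is scaled so the largest magnitude sample equals
    ``amplitude_lsb`` exactly before quantization, making the true peak
    amplitude ``20*log10(amplitude_lsb)``.  Ground truth also records the
    95%-power tonal frequency and the mean-square power of the loudest
    20 ms window.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    x = np.zeros(n)
    for freq, rel_power in spec.tones:
        phase = rng.uniform(0, 2 * np.pi)
        x += np.sqrt(2 * rel_power) * np.sin(2 * np.pi * freq * t + phase)
    peak = np.abs(x).max()
    if peak > 0:
        x *= spec.amplitude_lsb / peak
    if spec.noise_db is not None:
        x += 10 ** (spec.noise_db / 20) * rng.standard_normal(n)
    full_scale = 2 ** (spec.bit_depth - 1) - 1
    samples = np.clip(np.rint(x), -full_scale, full_scale).astype(np.int64)
    n_forced = int(round(spec.clip_fraction * n))
    if n_forced:
        idx = rng.choice(n, size=n_forced, replace=False)
        samples[idx] = np.where(samples[idx] >= 0, full_scale, -full_scale)

    frame_len = int(round(0.020 * spec.sample_rate))
    hop = frame_len // 2
    if n >= frame_len:
        xs = samples.astype(np.float64)
        powers = [
            np.mean(xs[s:s + frame_len] ** 2)
            for s in range(0, n - frame_len + 1, hop)
        ]
        true_power_db = 10 * np.log10(max(powers))
    else:
        true_power_db = float("nan")
    truth = {
        "true_peak_frequency_hz": _true_peak_frequency(spec.tones),
        "true_peak_amplitude_db": 20 * np.log10(
            np.abs(samples).max()) if np.any(samples) else float("nan"),
        "true_peak_power_db": true_power_db,
        "n_forced_clips": n_forced,
    }
    dtype = np.int16 if spec.bit_depth <= 16 else np.int32
    return (
        AudioSignal(samples.astype(dtype), spec.sample_rate, spec.bit_depth),
        truth,
    )


def generate_feeding_session(
    n_swallows: int = 20,
    session_s: float = 120.0,
    sample_rate: int = 44_100,
    noise_db: float = 30.0,
    seed: int = 0,
    recording_id: str = "session",
) -> tuple[AudioSignal, pd.DataFrame]:
    """A 2-minute feeding observation: disjoint swallow bursts over noise.

    Burst durations, tone frequencies and amplitudes are drawn around the
    cohort set-points (0.85 +- 0.31 s, 1678 +- 414 Hz, ~30000 LSB).  The
    returned annotation table has one row per burst and matches the burst
    placements exactly.
    """
    rng = np.random.default_rng(seed)
    if n_swallows < 0:
        raise ValueError("n_swallows must be >= 0")
    durations = np.clip(rng.normal(0.85, 0.31, n_swallows), 0.30, 1.50)
    if durations.sum() > session_s:
        raise ValueError(
            f"{n_swallows} swallows totalling {durations.sum():.1f} s do "
            f"not fit in a {session_s:.0f} s session"
        )
    # random disjoint placement: split the leftover time into n+1 gaps
    gap_weights = rng.dirichlet(np.ones(n_swallows + 1)) if n_swallows else []
    slack = session_s - durations.sum()
    n_total = int(round(session_s * sample_rate))
    noise_rms = 10 ** (noise_db / 20)
    samples = np.rint(noise_rms * rng.standard_normal(n_total))

    rows = []
    cursor = 0.0
    for i in range(n_swallows):
        cursor += slack * gap_weights[i]
        start_s, dur = cursor, float(durations[i])
        freq = float(np.clip(rng.normal(1678.3, 413.5), 500.0, 4000.0))
        amp = int(np.clip(rng.normal(30_000, 2_000), 15_000, 32_000))
        burst, _ = generate_swallow_audio(SwallowSoundSpec(
            duration_s=dur, sample_rate=sample_rate, tones=((freq, 1.0),),
            amplitude_lsb=amp, noise_db=None,
            seed=int(rng.integers(2**31)),
        ))
        start_idx = int(np.floor(start_s * sample_rate + 0.5))
        end_idx = start_idx + burst.n_samples
        samples[start_idx:end_idx] += burst.samples
        rows.append({
            "recording_id": recording_id,
            "swallow_id": f"sw{i + 1:03d}",
            "start_s": start_idx / sample_rate,
            "end_s": end_idx / sample_rate,
        })
        cursor = start_s + dur
    samples = np.clip(samples, -32_767, 32_767).astype(np.int16)
    annotations = pd.DataFrame(
        rows, columns=["recording_id", "swallow_id", "start_s", "end_s"]
    )
    return AudioSignal(samples, sample_rate, 16), annotations


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort conditions.

    Defaults reproduce the published cohort: 80 neonates, the Table-style
    per-parameter presence prevalences, 0.9 marginal rater agreement, and a
    0.24 Pearson correlation between comorbidity count and peak amplitude.
    """

    n_neonates: int = 80
    prevalence: dict = field(
        default_factory=lambda: dict(TABLE3_PREVALENCE))
    agreement: float = 0.9
    target_correlation: float = 0.24
    comorbidity_mean: float = 2.4
    n_swallows_per_file: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neonates < 1:
            raise ValueError("n_neonates must be >= 1")
        if not 0 <= self.agreement <= 1:
            raise ValueError("agreement must be a probability")
        for key, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence {p} for {key} outside [0, 1]")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


@lru_cache(maxsize=None)
def _copula_attenuation(lam: float) -> float:
    """corr(F_Poisson^-1(Phi(Z)), Z) for Z ~ N(0,1), by quadrature.

    A Gaussian copula over a discrete margin attenuates the linear
    correlation; dividing the target by this factor compensates.
    """
    z = np.linspace(-8, 8, 20001)
    phi = stats.norm.pdf(z)
    g = stats.poisson.ppf(stats.norm.cdf(z), lam)
    mean = np.trapezoid(g * phi, z)
    var = np.trapezoid((g - mean) ** 2 * phi, z)
    cov = np.trapezoid((g - mean) * z * phi, z)
    return cov / np.sqrt(var)


def _draw_ratings(
    rng: np.random.Generator, spec: CohortSpec, neonate_id: str
) -> PerceptualProfile:
    """One consensus profile: per-swallow presence collapsed per parameter."""
    ratings = {}
    for phase, names in PARAMETER_INVENTORY.items():
        for name in names:
            p = spec.prevalence.get((phase.value, name), 0.0)
            if phase is Phase.DURING:
                # per-neonate presence rate p; if present, the sound recurs
                # over individual swallows with high per-swallow probability
                if rng.uniform() < p:
                    per_swallow = rng.uniform() < 0.95
                    vec = rng.uniform(
                        size=spec.n_swallows_per_file) < (0.95 if per_swallow
                                                          else 0.5)
                    vec[int(rng.integers(spec.n_swallows_per_file))] = True
                    ratings[(phase, name)] = presence_from_swallows(vec)
                else:
                    ratings[(phase, name)] = Rating(RatingValue.NO)
            else:
                value = (RatingValue.YES if rng.uniform() < p
                         else RatingValue.NO)
                ratings[(phase, name)] = Rating(value)
    return PerceptualProfile(neonate_id, "consensus", ratings)


def generate_rating_pair(spec: CohortSpec) -> pd.DataFrame:
    """Two-rater long-format rating table with controlled agreement.

    Rater A draws each parameter from its prevalence; rater B copies A with
    probability ``spec.agreement`` and takes the opposite value otherwise,
    independently per parameter and neonate.
    """
    rng = _substreams(spec.seed, 3)[1]  # named substream: ratings
    rows = []
    for i in range(spec.n_neonates):
        neonate = f"n{i + 1:03d}"
        for phase, names in PARAMETER_INVENTORY.items():
            for name in names:
                p = spec.prevalence.get((phase.value, name), 0.0)
                a = "yes" if rng.uniform() < p else "no"
                if rng.uniform() < spec.agreement:
                    b = a
                else:
                    b = "no" if a == "yes" else "yes"
                for rater, value in (("rater_a", a), ("rater_b", b)):
                    rows.append({
                        "neonate_id": neonate, "rater_id": rater,
                        "phase": phase.value, "parameter": name,
                        "value": value, "consistent": "",
                    })
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, list[PerceptualProfile], pd.DataFrame]:
    """Cohort covariates, consensus perceptual profiles and feature means.

    Comorbidity counts (Poisson margin) and per-neonate mean peak amplitude
    (normal margin, 89.67 +- 1.1 dB) are coupled through a Gaussian copula
    whose latent correlation is inflated to offset the discrete-margin
    attenuation, so the sampled Pearson correlation targets
    ``spec.target_correlation``.  Coordination labels are produced by
    running the rule classifier on the generated ratings, never sampled
    directly.
    """
    rng_cov, rng_rate, _ = _substreams(spec.seed, 3)
    n = spec.n_neonates
    target = spec.target_correlation
    atten = _copula_attenuation(spec.comorbidity_mean)
    if abs(target) > atten:
        raise ValueError(
            f"target correlation {target} infeasible for a Poisson"
            f"({spec.comorbidity_mean}) margin; |r| must be <= {atten:.3f}"
        )
    rho_z = target / atten
    z = rng_cov.multivariate_normal(
        [0, 0], [[1, rho_z], [rho_z, 1]], size=n)
    comorbidities = stats.poisson.ppf(
        stats.norm.cdf(z[:, 0]), spec.comorbidity_mean).astype(int)
    amplitude = 89.67 + 1.1 * z[:, 1]

    duration = np.clip(rng_cov.normal(0.85, 0.31, n), 0.2, None)
    frequency = np.clip(rng_cov.normal(1678.3, 413.5, n), 400, None)
    power = np.minimum(rng_cov.normal(80.83, 4.8, n), amplitude - 0.1)
    birth_ga = np.clip(rng_cov.normal(33.4, 2.6, n), 25, 36)
    chron_ga = np.clip(birth_ga + rng_cov.normal(3.6, 1.0, n), 34, 43)

    profiles = [
        _draw_ratings(rng_rate, spec, f"n{i + 1:03d}") for i in range(n)
    ]
    coordination = [classify_coordination(p).value for p in profiles]

    ids = [f"n{i + 1:03d}" for i in range(n)]
    cohort = pd.DataFrame({
        "neonate_id": ids,
        "birth_gestation_weeks": np.round(birth_ga, 1),
        "chronological_gestation_weeks": np.round(chron_ga, 1),
        "n_medical_conditions": comorbidities,
        "coordination": coordination,
    })
    features = pd.DataFrame({
        "neonate_id": ids,
        "duration_s": duration,
        "peak_frequency_hz": frequency,
        "peak_amplitude_db": amplitude,
        "peak_power_db": power,
    })
    return cohort, profiles, features
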