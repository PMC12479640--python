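"""Acoustic swallow-sound features: duration, peak frequency, amplitude, power.

The feature definitions follow the cervical-auscultation analysis pipeline:

* the segment is high-pass filtered (4th-order Butterworth, 400 Hz cutoff)
  to discard low-frequency feeding-movement energy;
* the filtered signal is split into 20 ms frames with 50% overlap;
* each frame's power spectral density is a Welch estimate (10 Hann-windowed
  sub-frames, 50% overlap), normalized to unit sum;
* **peak frequency** is read off the maximum-energy frame as the smallest
  grid frequency at which the cumulative normalized PSD reaches 95% of the
  total power;
* **peak amplitude** is ``20*log10(max |sample|)`` of the raw segment;
* **peak power** is the largest per-frame mean-square power (in dB re
  1 LSB^2), with clipped samples removed from both the energy sum and the
  effective frame duration so saturation does not bias the estimate.

All decibel values are referenced to one quantization step (LSB) of the
integer PCM encoding: 0 dB = 1 LSB, and 16-bit full scale is 90.31 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .audio_io import (
    AudioSignal,
    ClipMask,
    SwallowInterval,
    detect_clips,
    extract_segment,
)

__all__ = [
    "FilterSpec",
    "FrameSpec",
    "SpectralEstimate",
    "AcousticProfile",
    "FeatureUndefinedError",
    "highpass",
    "frame",
    "welch_psd",
    "peak_frequency",
    "peak_amplitude_db",
    "peak_power_db",
    "extract_profile",
    "extract_features",
    "load_config",
]

FEATURE_COLUMNS = [
    "recording_id",
    "swallow_id",
    "duration_s",
    "peak_frequency_hz",
    "peak_amplitude_db",
    "peak_power_db",
    "n_clipped_removed",
]


class FeatureUndefinedError(ValueError):
    """A feature is undefined for this segment (zero energy, all clipped...)."""


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth pre-filter (defaults: order 4, 400 Hz).

    ``zero_phase=False`` applies the filter forward-only (causal); the
    zero-phase forward-backward variant squares the magnitude response and
    is available behind the flag for comparison studies.
    """

    cutoff_hz: float = 400.0
    order: int = 4
    zero_phase: bool = False

    def sos(self, sample_rate: float) -> np.ndarray:
        if not 0 < self.cutoff_hz < sample_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, fs/2) "
                f"for fs={sample_rate}"
            )
        return sps.butter(
            self.order, self.cutoff_hz, btype="highpass", fs=sample_rate,
            output="sos",
        )


@dataclass(frozen=True)
class FrameSpec:
    """Short-time framing and Welch sub-framing parameters.

    Defaults: 20 ms frames, 50% overlap, 10 Welch sub-frames at 50%
    overlap.  The sub-frame length is ``floor(2L/(n_subframes+1))`` so the
    half-overlapping sub-frames exactly tile the frame (for 10 sub-frames
    this is ``floor(L/5.5)``).
    """

    frame_ms: float = 20.0
    overlap_fraction: float = 0.5
    welch_subframes: int = 10
    welch_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.welch_subframes < 2:
            raise ValueError("need at least 2 Welch sub-frames")

    def frame_length(self, sample_rate: float) -> int:
        return int(round(self.frame_ms * sample_rate / 1000.0))

    def hop(self, sample_rate: float) -> int:
        L = self.frame_length(sample_rate)
        return max(1, int(round(L * (1 - self.overlap_fraction))))

    def subframe_length(self, frame_length: int) -> int:
        # n half-overlapping sub-frames of length l tile L = l*(n+1)/2
        denom = 1 + (self.welch_subframes - 1) * (1 - self.welch_overlap_fraction)
        return int(frame_length / denom)


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided PSD on an ascending frequency grid spanning [0, fs/2]."""

    frequencies_hz: np.ndarray
    psd: np.ndarray
    normalized: bool = False
    zero_energy: bool = False


@dataclass(frozen=True)
class AcousticProfile:
    """Per-swallow acoustic feature vector; NaN fields carry a reason code."""

    duration_s: float
    peak_frequency_hz: float
    peak_amplitude_db: float
    peak_power_db: float
    n_clipped_removed: int = 0
    reasons: dict = field(default_factory=dict)


def highpass(signal: AudioSignal | np.ndarray, spec: FilterSpec,
             sample_rate: float | None = None) -> np.ndarray:
    """Apply the Butterworth high-pass; returns a float array, same length."""
    if isinstance(signal, AudioSignal):
        x = signal.samples.astype(np.float64)
        sample_rate = signal.sample_rate
    else:
        x = np.asarray(signal, dtype=np.float64)
        if sample_rate is None:
            raise ValueError("sample_rate required for raw arrays")
    if x.size <= 3 * spec.order:
        raise FeatureUndefinedError(
            f"segment of {x.size} samples too short to filter (order "
            f"{spec.order})"
        )
    sos = spec.sos(sample_rate)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def frame(x: np.ndarray, spec: FrameSpec, sample_rate: float,
          return_starts: bool = False):
    """Split ``x`` into overlapping frames; trailing partial frame dropped.

    Frame count is ``1 + floor((N - L) / hop)``.  Segments shorter than one
    frame are rejected rather than zero-padded (padding biases power
    downward).
    """
    x = np.asarray(x)
    L = spec.frame_length(sample_rate)
    hop = spec.hop(sample_rate)
    if x.size < L:
        raise FeatureUndefinedError(
            f"segment of {x.size} samples is shorter than one "
            f"{spec.frame_ms:g} ms frame ({L} samples); pad or reject"
        )
    n_frames = 1 + (x.size - L) // hop
    starts = np.arange(n_frames) * hop
    frames = np.stack([x[s:s + L] for s in starts])
    if return_starts:
        return frames, starts
    return frames


def welch_psd(frame_x: np.ndarray, spec: FrameSpec,
              sample_rate: float) -> SpectralEstimate:
    """Welch PSD of one frame, normalized to unit sum.

    Hann-windowed modified periodograms of ``welch_subframes``
    half-overlapping sub-frames are averaged; no detrending.  An all-zero
    frame yields a ``zero_energy``-flagged estimate (no uniform PSD is
    substituted).
    """
    x = np.asarray(frame_x, dtype=np.float64)
    nperseg = spec.subframe_length(x.size)
    if nperseg < 8:
        raise ValueError(
            f"frame of {x.size} samples gives sub-frames of {nperseg} "
            "samples (< 8); use longer frames or fewer sub-frames"
        )
    noverlap = int(nperseg * spec.welch_overlap_fraction)
    freqs, psd = sps.welch(
        x, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend=False, scaling="density",
    )
    total = psd.sum()
    if total <= 0:
        return SpectralEstimate(freqs, np.zeros_like(psd),
                                normalized=False, zero_energy=True)
    return SpectralEstimate(freqs, psd / total, normalized=True)


def _cdf_crossing(est: SpectralEstimate, threshold: float) -> float:
    cdf = np.cumsum(est.psd)
    idx = int(np.searchsorted(cdf, threshold - 1e-12))
    idx = min(idx, est.frequencies_hz.size - 1)
    return float(est.frequencies_hz[idx])


def peak_frequency(
    segment: AudioSignal,
    fspec: FilterSpec = FilterSpec(),
    frspec: FrameSpec = FrameSpec(),
    cdf_threshold: float = 0.95,
    mode: Literal["max_energy_frame", "pooled", "per_frame_max"] = "max_energy_frame",
) -> float:
    """Cumulative-power peak frequency of a swallow segment.

    Pipeline: high-pass -> frame -> Welch PSD -> cumulative sum from low to
    high frequency -> smallest grid frequency whose CDF reaches
    ``cdf_threshold`` (default 0.95).  By default the PSD comes from the
    single maximum-energy frame; ``pooled`` averages the per-frame PSDs and
    ``per_frame_max`` reports the largest per-frame crossing (both
    non-default variants).
    """
    if not 0 < cdf_threshold <= 1:
        raise ValueError("cdf_threshold must be in (0, 1]")
    y = highpass(segment, fspec)
    frames = frame(y, frspec, segment.sample_rate)
    energies = np.sum(frames ** 2, axis=1)
    if energies.max() <= 0:
        raise FeatureUndefinedError("zero-energy segment: peak frequency undefined")
    if mode == "max_energy_frame":
        est = welch_psd(frames[int(np.argmax(energies))], frspec,
                        segment.sample_rate)
        return _cdf_crossing(est, cdf_threshold)
    ests = [welch_psd(f, frspec, segment.sample_rate)
            for f in frames if np.any(f)]
    ests = [e for e in ests if not e.zero_energy]
    if mode == "pooled":
        pooled = np.mean([e.psd for e in ests], axis=0)
        pooled /= pooled.sum()
        est = SpectralEstimate(ests[0].frequencies_hz, pooled, normalized=True)
        return _cdf_crossing(est, cdf_threshold)
    if mode == "per_frame_max":
        return max(_cdf_crossing(e, cdf_threshold) for e in ests)
    raise ValueError(f"unknown mode {mode!r}")


def peak_amplitude_db(segment: AudioSignal) -> float:
    """``20*log10(max |sample|)`` in dB re 1 LSB, on the raw segment."""
    peak = int(np.abs(segment.samples.astype(np.int64)).max())
    if peak == 0:
        raise FeatureUndefinedError("all-zero segment: peak amplitude undefined")
    return 20.0 * np.log10(peak)


def peak_power_db(
    segment: AudioSignal,
    fspec: FilterSpec = FilterSpec(),
    frspec: FrameSpec = FrameSpec(),
    clip: ClipMask | None = None,
    filtered: bool = True,
) -> tuple[float, int]:
    """Clip-corrected peak frame power in dB re 1 LSB^2.

    Clipped samples are removed from the sample stream first (shortening
    the effective duration), the censored stream is high-pass filtered and
    framed, and each frame's power is its mean square — energy divided by
    effective duration.  The peak is the maximum over frames.  Returns
    ``(dB, n_clipped_removed)``.
    """
    if clip is None:
        clip = detect_clips(segment)
    keep = np.ones(segment.n_samples, dtype=bool)
    keep[clip.indices] = False
    censored = segment.samples[keep].astype(np.float64)
    L = frspec.frame_length(segment.sample_rate)
    if censored.size < L:
        raise FeatureUndefinedError(
            f"only {censored.size} unclipped samples remain "
            f"(< one {frspec.frame_ms:g} ms frame): peak power undefined"
        )
    if filtered:
        censored = highpass(censored, fspec, segment.sample_rate)
    frames = frame(censored, frspec, segment.sample_rate)
    power = np.mean(frames ** 2, axis=1)
    peak = float(power.max())
    if peak <= 0:
        raise FeatureUndefinedError("zero-energy segment: peak power undefined")
    return 10.0 * np.log10(peak), clip.n_clipped

def extract_profile(
    segment: AudioSignal,
    interval: SwallowInterval,
    fspec: FilterSpec = FilterSpec(),
    frspec: FrameSpec = FrameSpec(),
    clip_threshold: int | None = None,
    cdf_threshold: float = 0.95,
) -> AcousticProfile:
    """All four features for one annotated swallow.

    Duration is the annotated ``end_s - start_s``.  A feature that cannot
    be computed (segment too short, zero energy, fully clipped) becomes NaN
    with a reason code in ``profile.reasons`` rather than a silent drop.
    """
    reasons: dict[str, str] = {}
    clip = detect_clips(segment, clip_threshold)

    def attempt(name, fn):
        try:
            return fn()
        except FeatureUndefinedError as exc:
            reasons[name] = str(exc)
            return float("nan")

    amp = attempt("peak_amplitude_db", lambda: peak_amplitude_db(segment))
    freq = attempt(
        "peak_frequency_hz",
        lambda: peak_frequency(segment, fspec, frspec, cdf_threshold),
    )
    power = attempt(
        "peak_power_db",
        lambda: peak_power_db(segment, fspec, frspec, clip)[0],
    )
    return AcousticProfile(
        duration_s=interval.duration_s,
        peak_frequency_hz=freq,
        peak_amplitude_db=amp,
        peak_power_db=power,
        n_clipped_removed=clip.n_clipped,
        reasons=reasons,
    )


def extract_features(
    recording: AudioSignal,
    intervals: Iterable[SwallowInterval],
    fspec: FilterSpec = FilterSpec(),
    frspec: FrameSpec = FrameSpec(),
    clip_threshold: int | None = None,
    cdf_threshold: float = 0.95,
) -> pd.DataFrame:
    """Feature table (one row per annotated swallow) for a session recording."""
    rows = []
    for iv in intervals:
        seg = extract_segment(recording, iv)
        prof = extract_profile(seg, iv, fspec, frspec, clip_threshold,
                               cdf_threshold)
        rows.append({
            "recording_id": iv.recording_id,
            "swallow_id": iv.swallow_id,
            "duration_s": prof.duration_s,
            "peak_frequency_hz": prof.peak_frequency_hz,
            "peak_amplitude_db": prof.peak_amplitude_db,
            "peak_power_db": prof.peak_power_db,
            "n_clipped_removed": prof.n_clipped_removed,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON analysis config into (FilterSpec, FrameSpec, extras).

    Recognized keys: cutoff_hz, filter_order, zero_phase, frame_ms,
    overlap_fraction, welch_subframes, welch_overlap_fraction,
    cdf_threshold, clip_threshold, bit_depth.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fspec = FilterSpec(
        cutoff_hz=raw.get("cutoff_hz", 400.0),
        order=raw.get("filter_order", 4),
        zero_phase=raw.get("zero_phase", False),
    )
    frspec = FrameSpec(
        frame_ms=raw.get("frame_ms", 20.0),
        overlap_fraction=raw.get("overlap_fraction", 0.5),
        welch_subframes=raw.get("welch_subframes", 10),
        welch_overlap_fraction=raw.get("welch_overlap_fraction", 0.5),
    )
    extras = {
        "cdf_threshold": raw.get("cdf_threshold", 0.95),
        "clip_threshold": raw.get("clip_threshold"),
        "bit_depth": raw.get("bit_depth", 16),
    }
    return {"filter": fspec, "frames": frspec, **extras}
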