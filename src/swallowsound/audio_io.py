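"""WAV and annotation-table I/O for cervical-auscultation recordings.

Recordings are single-channel integer PCM WAV files (study standard:
16-bit, 44,100 Hz).  Swallow boundaries are supplied by a human-annotated
interval table; this module cuts the annotated segments out of the session
signal and flags clipped samples so downstream power estimates can censor
them.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AudioSignal",
    "SwallowInterval",
    "ClipMask",
    "UnsupportedFormatError",
    "read_wav",
    "write_wav",
    "extract_segment",
    "detect_clips",
    "read_annotations",
    "write_annotations",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["recording_id", "swallow_id", "start_s", "end_s"]

_WIDTH_TO_DTYPE = {2: np.int16, 4: np.int32}


class UnsupportedFormatError(ValueError):
    """Raised for WAV encodings outside integer PCM (float, compressed...)."""


@dataclass(frozen=True)
class AudioSignal:
    """Mono integer-PCM signal in quantization units (LSB).

    Amplitudes are kept as raw integer sample values so that the decibel
    reference (0 dB = 1 LSB) used by the acoustic features stays exact.
    """

    samples: np.ndarray
    sample_rate: int
    bit_depth: int = 16

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if samples.size < 1:
            raise ValueError("AudioSignal must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        full_scale = 2 ** (self.bit_depth - 1) - 1
        # signed PCM admits -(full_scale+1); ingestion clamps nothing, so only
        # check the magnitude bound that the bit depth implies
        if np.abs(samples.astype(np.int64)).max(initial=0) > full_scale + 1:
            raise ValueError(
                f"sample magnitudes exceed {self.bit_depth}-bit range"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def full_scale(self) -> int:
        """Largest positive sample value representable at this bit depth."""
        return 2 ** (self.bit_depth - 1) - 1


@dataclass(frozen=True)
class SwallowInterval:
    """One annotated swallow: [start_s, end_s) within a named recording."""

    recording_id: str
    swallow_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}): "
                "need 0 <= start < end"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ClipMask:
    """Indices of samples whose magnitude reached the clip threshold."""

    indices: np.ndarray
    clip_threshold: int

    @property
    def n_clipped(self) -> int:
        return int(self.indices.size)


def read_wav(path: str | Path) -> AudioSignal:
    """Read an integer-PCM WAV file as a mono :class:`AudioSignal`.

    Stereo input keeps channel 0 (the study used a single neck microphone);
    a warning is logged.  Float or compressed encodings are rejected so the
    LSB decibel reference stays well defined.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as wav:
            n_channels = wav.getnchannels()
            sampwidth = wav.getsampwidth()
            sample_rate = wav.getframerate()
            n_frames = wav.getnframes()
            if wav.getcomptype() != "NONE":
                raise UnsupportedFormatError(
                    f"{path}: compressed WAV ({wav.getcomptype()}) unsupported"
                )
            raw = wav.readframes(n_frames)
    except wave.Error as exc:  # non-PCM format chunks land here
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if n_frames == 0:
        raise UnsupportedFormatError(f"{path}: empty WAV file")
    if sampwidth not in _WIDTH_TO_DTYPE:
        raise UnsupportedFormatError(
            f"{path}: {8 * sampwidth}-bit PCM unsupported (use 16- or 32-bit)"
        )
    data = np.frombuffer(raw, dtype=_WIDTH_TO_DTYPE[sampwidth])
    if n_channels > 1:
        logger.warning(
            "%s has %d channels; keeping channel 0", path, n_channels
        )
        data = data[::n_channels]
    return AudioSignal(
        samples=data.copy(), sample_rate=sample_rate, bit_depth=8 * sampwidth
    )


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a mono integer-PCM WAV; inverse of :func:`read_wav`."""
    if signal.bit_depth not in (16, 32):
        raise UnsupportedFormatError(
            f"cannot write {signal.bit_depth}-bit PCM (use 16 or 32)"
        )
    dtype = _WIDTH_TO_DTYPE[signal.bit_depth // 8]
    with wave.open(str(path), "wb") as wav:
        wav.setnchannels(1)
        wav.setsampwidth(signal.bit_depth // 8)
        wav.setframerate(signal.sample_rate)
        wav.writeframes(np.ascontiguousarray(signal.samples, dtype=dtype))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def extract_segment(signal: AudioSignal, interval: SwallowInterval) -> AudioSignal:
    """Cut the half-open sample window [round(start*fs), round(end*fs)).

    Boundaries use round-half-up of time x rate so that adjacent intervals
    tile a session without gaps or overlap.
    """
    fs = signal.sample_rate
    start = _round_half_up(interval.start_s * fs)
    end = _round_half_up(interval.end_s * fs)
    if end > signal.n_samples:
        raise ValueError(
            f"interval {interval.swallow_id} [{interval.start_s}, "
            f"{interval.end_s}) s extends past the recording "
            f"({signal.duration_s:.3f} s)"
        )
    return AudioSignal(
        samples=signal.samples[start:end],
        sample_rate=fs,
        bit_depth=signal.bit_depth,
    )


def detect_clips(signal: AudioSignal, clip_threshold: int | None = None) -> ClipMask:
    """Flag every sample with ``|sample| >= clip_threshold``.

    The default threshold is full scale (2^(bits-1) - 1, i.e. 32767 for
    16-bit); lower it for recorders that saturate below full scale.
    """
    if clip_threshold is None:
        clip_threshold = signal.full_scale
    if clip_threshold < 1:
        raise ValueError("clip_threshold must be >= 1")
    idx = np.nonzero(
        np.abs(signal.samples.astype(np.int64)) >= clip_threshold
    )[0]
    return ClipMask(indices=idx, clip_threshold=clip_threshold)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a swallow-interval table (CSV: recording_id,swallow_id,start_s,end_s)."""
    df = pd.read_csv(path, dtype={"recording_id": str, "swallow_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation CSV missing columns {missing}")
    bad = df[~(df["start_s"] < df["end_s"]) | (df["start_s"] < 0)]
    if not bad.empty:
        rows = ", ".join(str(i) for i in bad.index[:5])
        raise ValueError(f"{path}: invalid intervals at rows {rows}")
    return df[ANNOTATION_COLUMNS]


def write_annotations(path: str | Path, intervals: pd.DataFrame) -> None:
    intervals[ANNOTATION_COLUMNS].to_csv(path, index=False)


def intervals_from_frame(df: pd.DataFrame) -> list[SwallowInterval]:
    """Convert an annotation table into :class:`SwallowInterval` objects."""
    return [
        SwallowInterval(
            recording_id=str(r.recording_id),
            swallow_id=str(r.swallow_id),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
        )
        for r in df.itertuples(index=False)
    ]
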