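"""Synthetic multi-subject wrist-IMU cohorts with labelled activity bouts.

Each subject's recording is a continuous 6-channel stream (3-axis
accelerometer + 3-axis gyroscope at a fixed sampling rate, 50 Hz by
default) in which activity bouts — subject-modulated sums of sinusoids
plus Gaussian noise — are separated by background gaps containing noise
only.  Bout annotations are emitted as half-open, 0-based sample-index
intervals, one activity per bout.

Randomness is hierarchical: a single root seed is split per subject via
a stable hash of the subject id, so adding subjects to a cohort never
perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Reserved label for unannotated stretches between bouts.
BACKGROUND = "background"

#: Channel order of a generated stream.
DEFAULT_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: Channel-group boundaries: accelerometer = channels 0..2, gyroscope = 3..5.
_GROUP_SLICES = (slice(0, 3), slice(3, 6))


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration (e.g. empty registry)."""


class SchedulingError(RuntimeError):
    """Raised when scheduled bouts cannot fit in the allotted stream."""


@dataclass(frozen=True)
class ActivityTemplate:
    """Generative description of one activity.

    ``base_frequencies`` and ``amplitudes`` are indexed by channel group
    (accelerometer first, then gyroscope); each group carries a list of
    oscillation frequencies in Hz sharing that group's amplitude.
    """

    name: str
    activity_type: str  # "playful" | "everyday"
    base_frequencies: tuple[tuple[float, ...], ...]
    amplitudes: tuple[float, ...]
    bout_duration: tuple[float, float]  # (mean s, sd s)
    repeats_per_subject: tuple[int, int]  # (min, max), inclusive
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.activity_type not in ("playful", "everyday"):
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        if len(self.base_frequencies) != len(self.amplitudes):
            raise ValueError("one amplitude per channel group required")
        for freqs in self.base_frequencies:
            for f in freqs:
                if f <= 0:
                    raise ValueError(f"frequency must be positive, got {f}")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if self.bout_duration[0] <= 0:
            raise ValueError("bout_duration mean must be > 0")
        lo, hi = self.repeats_per_subject
        if lo > hi or lo < 0:
            raise ValueError("repeats_per_subject must satisfy 0 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_tempo(self, factor: float, name: str) -> "ActivityTemplate":
        """A copy executed at ``factor`` times the speed (same amplitudes)."""
        scaled = tuple(
            tuple(f * factor for f in freqs) for freqs in self.base_frequencies
        )
        return replace(self, name=name, base_frequencies=scaled)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject execution style modifiers."""

    subject_id: str
    gain: tuple[float, ...]  # per-channel multiplicative factor
    tempo: float  # multiplicative frequency factor
    phase_offset: float  # radians

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain must be > 0")
        if self.tempo <= 0:
            raise ValueError("tempo must be > 0")


@dataclass
class IMUStream:
    """One subject's fixed-rate multichannel recording."""

    subject_id: str
    sampling_rate: float
    channels: tuple[str, ...]
    samples: np.ndarray  # (T, n_channels)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channels):
            raise ValueError("samples must be (T, n_channels)")
        if len(self.channels) < 6:
            raise ValueError("at least 6 channels required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stream contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class LabelInterval:
    """A video-coded bout: half-open 0-based sample range on one stream."""

    subject_id: str
    activity: str
    start_index: int
    end_index: int
    bout_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"invalid interval [{self.start_index}, {self.end_index})"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation parameters."""

    activities: tuple[ActivityTemplate, ...]
    n_subjects: int
    sampling_rate: float = 50.0
    gap_duration: tuple[float, float] = (0.5, 2.0)  # uniform range, seconds
    gain_sd: float = 0.15  # lognormal sigma of per-channel gain
    tempo_sd: float = 0.05  # lognormal sigma of subject tempo
    background_noise_sd: float = 0.05
    max_duration_s: float | None = None  # cap on stream length, if any
    extra_channels: tuple[str, ...] = ()  # optional noise-only channels

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.n_subjects > 0 and len(self.activities) == 0:
            raise ConfigurationError("activity registry is empty")
        if self.gap_duration[0] < 0 or self.gap_duration[1] < self.gap_duration[0]:
            raise ConfigurationError("gap_duration must satisfy 0 <= lo <= hi")

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i:03d}" for i in range(self.n_subjects))


def _subject_seed(root_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject seed stream: root seed + CRC32 of the subject id."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(subject_id.encode())])


def draw_profile(
    subject_id: str, config: GeneratorConfig, rng: np.random.Generator
) -> SubjectProfile:
    n_ch = 6 + len(config.extra_channels)
    gain = tuple(np.exp(rng.normal(0.0, config.gain_sd, size=n_ch)))
    tempo = float(np.exp(rng.normal(0.0, config.tempo_sd)))
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    return SubjectProfile(subject_id, gain, tempo, phase)


def activity_signal(
    template: ActivityTemplate,
    profile: SubjectProfile,
    n_samples: int,
    rng: np.random.Generator,
    sampling_rate: float = 50.0,
) -> np.ndarray:
    """Generate ``n_samples`` x 6 samples of one bout of ``template``.

    The deterministic part is a sum of sinusoids at the template's
    per-group frequencies, scaled by the group amplitude and the
    subject's per-channel gain, frequency-warped by the subject's tempo,
    and phase-shifted per channel so the axes are not identical.
    Gaussian noise with sd ``template.noise_sd`` is added on top.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    nyquist = sampling_rate / 2.0
    t = np.arange(n_samples) / sampling_rate
    out = np.zeros((n_samples, 6))
    for g, group in enumerate(_GROUP_SLICES):
        amp = template.amplitudes[g]
        for i, f in enumerate(template.base_frequencies[g]):
            f_eff = f * profile.tempo
            if f_eff >= nyquist:
                raise ValueError(
                    f"effective frequency {f_eff:.3f} Hz (base {f} Hz x tempo "
                    f"{profile.tempo:.3f}) reaches Nyquist {nyquist} Hz"
                )
            for c in range(group.start, group.stop):
                # deterministic per-channel/component phase decorrelates axes
                phase = profile.phase_offset + 0.9 * c + 0.37 * np.pi * i
                out[:, c] += (
                    amp
                    * profile.gain[c]
                    * np.sin(2.0 * np.pi * f_eff * t + phase)
                )
    if template.noise_sd > 0:
        out += rng.normal(0.0, template.noise_sd, size=out.shape)
    return out


def _schedule_bouts(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[ActivityTemplate, int]]:
    """Draw and shuffle the per-subject bout plan: (template, n_samples)."""
    fs = config.sampling_rate
    bouts: list[tuple[ActivityTemplate, int]] = []
    for tpl in config.activities:
        lo, hi = tpl.repeats_per_subject
        n_rep = int(rng.integers(lo, hi + 1))
        mean_s, sd_s = tpl.bout_duration
        durs = rng.normal(mean_s, sd_s, size=n_rep)
        durs = np.clip(durs, 0.2, None)
        for d in durs:
            bouts.append((tpl, max(2, int(round(d * fs)))))
    order = rng.permutation(len(bouts))
    return [bouts[i] for i in order]


def generate_subject(
    subject_id: str, config: GeneratorConfig, root_seed: int
) -> tuple[IMUStream, list[LabelInterval]]:
    """Generate one subject's stream and bout annotations."""
    rng = np.random.default_rng(_subject_seed(root_seed, subject_id))
    profile = draw_profile(subject_id, config, rng)
    bouts = _schedule_bouts(config, rng)
    fs = config.sampling_rate
    gap_lo, gap_hi = config.gap_duration

    pieces: list[np.ndarray] = []
    labels: list[LabelInterval] = []
    cursor = 0

    def gap() -> None:
        nonlocal cursor
        n = max(1, int(round(rng.uniform(gap_lo, gap_hi) * fs)))
        pieces.append(rng.normal(0.0, config.background_noise_sd, size=(n, 6)))
        cursor += n

    gap()
    for k, (tpl, n_samp) in enumerate(bouts):
        if (
            config.max_duration_s is not None
            and cursor + n_samp > int(config.max_duration_s * fs)
        ):
            raise SchedulingError(
                f"subject {subject_id}: bout of {tpl.name!r} ({n_samp} samples) "
                f"exceeds stream capacity of {config.max_duration_s} s"
            )
        sig = activity_signal(tpl, profile, n_samp, rng, sampling_rate=fs)
        sig += rng.normal(0.0, config.background_noise_sd, size=sig.shape)
        pieces.append(sig)
        labels.append(
            LabelInterval(
                subject_id=subject_id,
                activity=tpl.name,
                start_index=cursor,
                end_index=cursor + n_samp,
                bout_id=f"{subject_id}_b{k:05d}",
            )
        )
        cursor += n_samp
        gap()

    samples = np.vstack(pieces) if pieces else np.zeros((0, 6))
    channels = DEFAULT_CHANNELS + config.extra_channels
    if config.extra_channels:
        extra = rng.normal(
            0.0, config.background_noise_sd, size=(samples.shape[0], len(config.extra_channels))
        )
        samples = np.hstack([samples, extra])
    stream = IMUStream(
        subject_id=subject_id,
        sampling_rate=fs,
        channels=channels,
        samples=samples,
    )
    return stream, labels


def generate_cohort(
    config: GeneratorConfig, seed: int
) -> tuple[list[IMUStream], list[LabelInterval]]:
    """Generate the whole cohort; identical (config, seed) is byte-identical."""
    streams: list[IMUStream] = []
    labels: list[LabelInterval] = []
    for sid in config.subject_ids:
        stream, subj_labels = generate_subject(sid, config, seed)
        streams.append(stream)
        labels.extend(subj_labels)
    return streams, labels


def bout_counts(labels: Sequence[LabelInterval]) -> dict[str, int]:
    """Positive bout count per activity over a cohort's annotations."""
    counts: dict[str, int] = {}
    for iv in labels:
        counts[iv.activity] = counts.get(iv.activity, 0) + 1
    return counts
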