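"""Synthetic EEG cohorts and loudness-rating traces.

Emulates the study design the pipeline expects: per subject, one 64-channel
15-s recording at 256 Hz for each (condition in {AM, C}) x (timepoint in
{T1, T2}), plus per-minute tinnitus loudness ratings from which the
responder/non-responder label follows.

Signal model per channel: pink (1/f) background noise plus five band-limited
oscillations (centre frequencies 2, 6, 10, 20, 40 Hz) whose amplitudes and
phases are redrawn each 192-sample block, plus a shared 10 Hz source mixed
into the eight temporal-site channels with a gain that carries the class
effect: ``g = g0 * (1 + effect_size * delta)`` with delta = +1 for
responders at T1, -1 (AM) / -2 (C) for responders at T2, and 0 for
non-responders.  Block-wise redrawing keeps the 192-point analysis segments
exchangeable, so with ``effect_size = 0`` the classes are indistinguishable
and samples carry no persistent subject signature.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS_64, TEMPORAL_CHANNELS
from .io import CONDITIONS, TIMEPOINTS, EEGRecording
from .stats import NONRESPONDER, RESPONDER, LoudnessSeries

BLOCK = 192  # samples; matches the analysis window
BAND_FREQS = (2.0, 6.0, 10.0, 20.0, 40.0)  # delta, theta, alpha, beta, gamma
BAND_AMPS = (0.8, 0.6, 1.0, 0.4, 0.2)
SHARED_GAIN = 1.0  # g0: baseline coupling gain of the shared temporal source

#: class/timepoint modulation of the temporal-site coupling gain
DELTA = {
    (RESPONDER, "T1", "AM"): 1.0,
    (RESPONDER, "T1", "C"): 1.0,
    (RESPONDER, "T2", "AM"): -1.0,
    (RESPONDER, "T2", "C"): -2.0,
    (NONRESPONDER, "T1", "AM"): 0.0,
    (NONRESPONDER, "T1", "C"): 0.0,
    (NONRESPONDER, "T2", "AM"): 0.0,
    (NONRESPONDER, "T2", "C"): 0.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort."""

    n_responders: int = 6
    n_nonresponders: int = 3
    fs: float = 256.0
    duration: float = 15.0
    n_channels: int = 64
    effect_size: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders + self.n_nonresponders < 2:
            raise ValueError("need at least 2 subjects")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer number of samples")
        if not 1 <= self.n_channels <= 64:
            raise ValueError("n_channels must be in [1, 64]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class SubjectRecordingSet:
    """All recordings and loudness traces for one subject."""

    subject_id: str
    label: str
    recordings: dict[tuple[str, str], EEGRecording]
    loudness: dict[str, LoudnessSeries] = field(default_factory=dict)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-shaped noise of length n with standard deviation sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_recording(
    spec: CohortSpec,
    label: str,
    timepoint: str,
    condition: str,
    subject_seed: int,
    subject_id: str = "S00",
) -> EEGRecording:
    """One synthetic EEG recording (fs*duration x n_channels), deterministic
    given ``(spec, subject_seed)``."""
    if label not in (RESPONDER, NONRESPONDER):
        raise ValueError(f"unknown label {label!r}")
    if timepoint not in TIMEPOINTS or condition not in CONDITIONS:
        raise ValueError("timepoint must be T1/T2 and condition AM/C")
    rng = np.random.default_rng(subject_seed)
    n = spec.n_samples
    channels = CHANNELS_64[: spec.n_channels]
    t = np.arange(n) / spec.fs
    data = np.empty((n, len(channels)))

    n_blocks = int(np.ceil(n / BLOCK))
    # per-block, per-channel, per-band amplitude factors and phases
    amp = rng.uniform(0.5, 1.5, size=(n_blocks, len(channels), len(BAND_FREQS)))
    phase = rng.uniform(0, 2 * np.pi, size=(n_blocks, len(channels), len(BAND_FREQS)))
    shared_phase = rng.uniform(0, 2 * np.pi, size=n_blocks)

    for c, _ in enumerate(channels):
        data[:, c] = _pink_noise(rng, n, spec.noise_sd)
    for b in range(n_blocks):
        sl = slice(b * BLOCK, min((b + 1) * BLOCK, n))
        tb = t[sl]
        for k, f in enumerate(BAND_FREQS):
            osc = np.sin(2 * np.pi * f * tb[:, None] + phase[b, :, k][None, :])
            data[sl] += BAND_AMPS[k] * amp[b, :, k][None, :] * osc

    gain = SHARED_GAIN * (1.0 + spec.effect_size * DELTA[(label, timepoint, condition)])
    temporal_idx = [channels.index(c) for c in TEMPORAL_CHANNELS if c in channels]
    if temporal_idx:
        source = np.empty(n)
        for b in range(n_blocks):
            sl = slice(b * BLOCK, min((b + 1) * BLOCK, n))
            source[sl] = np.sin(2 * np.pi * 10.0 * t[sl] + shared_phase[b])
        data[:, temporal_idx] += gain * source[:, None]

    return EEGRecording(
        data=data,
        fs=spec.fs,
        channel_labels=tuple(channels),
        meta={
            "subject": subject_id,
            "condition": condition,
            "timepoint": timepoint,
            "label": label,
        },
    )


def generate_loudness(label: str, condition: str, seed: int) -> LoudnessSeries:
    """Per-minute loudness ratings (1-9) over a 10-minute recording period.

    Minutes 0-5 are silent baseline (the stimulus plays during minute 5-6);
    minutes 6-10 follow stimulus offset.  Responders show a 1-5 unit drop at
    offset with stepwise recovery toward baseline; non-responders show zero
    or positive change.
    """
    if label not in (RESPONDER, NONRESPONDER):
        raise ValueError(f"unknown label {label!r}")
    if condition not in CONDITIONS:
        raise ValueError("condition must be AM or C")
    rng = np.random.default_rng(seed)
    base = int(rng.integers(4, 8))  # stable baseline loudness
    ratings = [base] * 6  # minutes 0..5 (final baseline at index 5)
    if label == RESPONDER:
        drop = int(rng.integers(1, 6))
        level = max(1, base - drop)
    else:
        change = int(rng.choice([0, 0, 0, 1, 2, 3]))
        level = min(9, base + change)
    for _ in range(6, 11):  # minutes 6..10: gradual return toward baseline
        ratings.append(level)
        if level < base:
            level += 1
        elif level > base:
            level -= 1
    phases = ["baseline"] * 6 + ["post"] * 5
    return LoudnessSeries(
        ratings=ratings,
        phases=phases,
        final_baseline_index=5,
        first_post_index=6,
        meta={"label": label, "condition": condition},
    )


def _derive_seed(root_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecordingSet]:
    """Generate the full cohort: per subject, 4 recordings (2 conditions x 2
    timepoints) and per-condition loudness traces consistent with the label."""
    cohort: list[SubjectRecordingSet] = []
    labels = [RESPONDER] * spec.n_responders + [NONRESPONDER] * spec.n_nonresponders
    for s_idx, label in enumerate(labels):
        subject_id = f"S{s_idx + 1:02d}"
        recordings: dict[tuple[str, str], EEGRecording] = {}
        for c_idx, condition in enumerate(CONDITIONS):
            for t_idx, timepoint in enumerate(TIMEPOINTS):
                seed = _derive_seed(spec.seed, s_idx, c_idx, t_idx)
                recordings[(condition, timepoint)] = generate_recording(
                    spec, label, timepoint, condition, seed, subject_id
                )
        loudness = {
            condition: generate_loudness(
                label, condition, _derive_seed(spec.seed, s_idx, c_idx, 99)
            )
            for c_idx, condition in enumerate(CONDITIONS)
        }
        cohort.append(
            SubjectRecordingSet(
                subject_id=subject_id,
                label=label,
                recordings=recordings,
                loudness=loudness,
            )
        )
    return cohort
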