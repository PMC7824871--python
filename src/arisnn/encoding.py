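"""Threshold-based spike encoding (TBR) of continuous EEG, and its inverse.

Each channel of a ``time x channel`` sample is differenced; an increase above
a per-channel threshold emits a +1 spike, a decrease below the negative
threshold emits a -1 spike, otherwise no spike.  The threshold is a multiple
(``alpha``) of the standard deviation of that channel's consecutive
differences, computed per sample so samples stay independent.  Decoding
reconstructs the signal by accumulating ``spike * threshold`` steps, which
bounds the per-step reconstruction error and provides a fidelity check.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EncodingParams:
    """Encoder settings.  ``alpha`` scales the per-channel difference SD."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")


@dataclass
class SpikeSample:
    """Ternary spike trains for one sample.

    ``spikes`` is channel x time over {-1, 0, +1}; ``thresholds`` holds the
    per-channel encoding threshold (0 only for zero-variance channels).
    """

    spikes: np.ndarray
    thresholds: np.ndarray
    channels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]


def encode_tbr(
    sample: np.ndarray,
    params: EncodingParams = EncodingParams(),
    channels: tuple[str, ...] | None = None,
    thresholds: np.ndarray | None = None,
    meta: dict | None = None,
) -> SpikeSample:
    """Encode a ``time x channel`` matrix into ternary spike trains.

    Per channel c the threshold is ``alpha * SD(diff(x_c))`` (population SD)
    unless ``thresholds`` overrides it.  The spike at time t >= 1 is +1 when
    ``x[t] - x[t-1]`` exceeds the threshold, -1 when it falls below the
    negative threshold, else 0; time 0 carries no spike.  Strict inequalities
    mean a constant channel (threshold 0) emits no spikes.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("sample must be a time x channel matrix with >= 2 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    n_time, n_ch = x.shape
    diffs = np.diff(x, axis=0)
    if thresholds is None:
        theta = params.alpha * diffs.std(axis=0)
    else:
        theta = np.asarray(thresholds, dtype=float)
        if theta.shape != (n_ch,):
            raise ValueError("thresholds shape must match channel count")
        if np.any(theta < 0):
            raise ValueError("thresholds must be >= 0")
    spikes = np.zeros((n_ch, n_time), dtype=np.int8)
    spikes[:, 1:] = (diffs > theta).T.astype(np.int8) - (diffs < -theta).T.astype(np.int8)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_ch))
    return SpikeSample(
        spikes=spikes, thresholds=theta, channels=tuple(channels), meta=dict(meta or {})
    )


def decode_tbr(spikes: SpikeSample, start_value: np.ndarray) -> np.ndarray:
    """Reconstruct a ``time x channel`` matrix from spike trains.

    ``x_hat[t] = x_hat[t-1] + spike[t] * threshold``, starting from
    ``start_value`` (one value per channel).
    """
    start = np.asarray(start_value, dtype=float)
    if start.shape != (spikes.n_channels,):
        raise ValueError("start_value must have one entry per channel")
    if spikes.thresholds.shape != (spikes.n_channels,):
        raise ValueError("thresholds/spikes shape mismatch")
    steps = spikes.spikes.astype(float) * spikes.thresholds[:, None]
    return (start[:, None] + np.cumsum(steps, axis=1)).T


def write_spikes_sparse(spikes: SpikeSample, path) -> None:
    """Serialize as sparse CSV rows (channel, time, polarity)."""
    ch_idx, t_idx = np.nonzero(spikes.spikes)
    df = pd.DataFrame(
        {
            "channel": [spikes.channels[i] for i in ch_idx],
            "time": t_idx,
            "polarity": spikes.spikes[ch_idx, t_idx],
        }
    )
    df.to_csv(path, index=False)


def write_spikes_dense(spikes: SpikeSample, path) -> None:
    """Serialize as a dense time x channel CSV of {-1, 0, +1}."""
    df = pd.DataFrame(spikes.spikes.T, columns=list(spikes.channels))
    df.to_csv(path, index=False)


def read_spikes_dense(path, thresholds: np.ndarray | None = None) -> SpikeSample:
    df = pd.read_csv(path)
    spikes = df.to_numpy(dtype=np.int8).T
    if not np.isin(spikes, (-1, 0, 1)).all():
        raise ValueError(f"{path}: spike file entries must be in {{-1, 0, +1}}")
    if thresholds is None:
        thresholds = np.zeros(spikes.shape[0])
    return SpikeSample(
        spikes=spikes, thresholds=np.asarray(thresholds, float),
        channels=tuple(df.columns),
    )
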