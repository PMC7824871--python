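"""Recording container, CSV I/O, segmentation, and dataset assembly.

EEG travels as plain CSV: a header row of channel labels and one row per
time sample, with a small key-value sidecar (``<file>.meta.txt``) holding the
sampling rate and subject/condition/timepoint metadata.  Files are reordered
to the canonical 64-channel order on read.
"""
from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import CHANNELS_64

log = logging.getLogger(__name__)

CONDITIONS = ("AM", "C")
TIMEPOINTS = ("T1", "T2")


@dataclass
class EEGRecording:
    """time x channel EEG matrix with sampling rate and metadata."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be time x channel")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count must match data columns")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class Sample:
    """One fixed-length segment ready for spike encoding."""

    data: np.ndarray  # window x channels
    subject: str
    condition: str
    timepoint: str
    index: int
    label: str | None = None

    @property
    def sample_id(self) -> str:
        return f"{self.subject}_{self.condition}_{self.timepoint}_s{self.index:02d}"


@dataclass
class Dataset:
    """Segmented samples grouped by (condition, timepoint), with labels."""

    samples: list[Sample]
    channel_labels: tuple[str, ...]
    exclusions: list[str] = field(default_factory=list)

    def select(self, condition: str | None = None, timepoint: str | None = None):
        out = [
            s
            for s in self.samples
            if (condition is None or s.condition == condition)
            and (timepoint is None or s.timepoint == timepoint)
        ]
        return out

    def subjects(self) -> list[str]:
        return list(dict.fromkeys(s.subject for s in self.samples))


def _meta_path(path) -> pathlib.Path:
    return pathlib.Path(str(path) + ".meta.txt")


def write_eeg_csv(rec: EEGRecording, path) -> None:
    pd.DataFrame(rec.data, columns=list(rec.channel_labels)).to_csv(path, index=False)
    with _meta_path(path).open("w") as fh:
        fh.write(f"fs: {rec.fs}\n")
        for key, value in rec.meta.items():
            fh.write(f"{key}: {value}\n")


def read_eeg_csv(path, meta: dict | None = None) -> EEGRecording:
    """Read and validate an EEG CSV, normalizing channel order.

    Requires exactly the canonical 64 channels (any order) and a fully
    numeric, finite body.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if sorted(cols) != sorted(CHANNELS_64):
        raise ValueError(
            f"{path}: expected the 64 canonical channels, got {len(cols)} columns"
        )
    df = df[list(CHANNELS_64)]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells")
    if np.isnan(values).any():
        raise ValueError(f"{path}: NaN values present")
    full_meta: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        for line in mp.read_text().splitlines():
            if ":" in line:
                k, v = line.split(":", 1)
                full_meta[k.strip()] = v.strip()
    if meta:
        full_meta.update(meta)
    fs = float(full_meta.pop("fs", 256.0))
    return EEGRecording(
        data=values, fs=fs, channel_labels=tuple(CHANNELS_64), meta=full_meta
    )


def segment_recording(rec: EEGRecording, window: int = 192) -> list[np.ndarray]:
    """Split into consecutive non-overlapping ``window``-sample segments.

    A trailing remainder shorter than one window is dropped (logged); a
    recording shorter than one window is an error.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = rec.n_samples
    if n < window:
        raise ValueError(f"recording has {n} samples; need at least {window}")
    n_seg = n // window
    dropped = n - n_seg * window
    if dropped:
        log.info("segmenting: dropping %d trailing samples", dropped)
    return [rec.data[i * window : (i + 1) * window] for i in range(n_seg)]


def assemble_dataset(cohort, exclusions: list[str] | None = None, window: int = 192) -> Dataset:
    """Segment a cohort into a labelled dataset, applying subject exclusions.

    ``cohort`` is a list of per-subject recording sets (``subject_id``,
    ``label``, ``recordings`` keyed by (condition, timepoint)).  Exclusions
    are applied before any modelling; unknown ids raise.
    """
    exclusions = list(exclusions or [])
    known = {s.subject_id for s in cohort}
    unknown = [e for e in exclusions if e not in known]
    if unknown:
        raise ValueError(f"exclusion list names unknown subjects: {unknown}")
    samples: list[Sample] = []
    channel_labels: tuple[str, ...] | None = None
    for subj in cohort:
        if subj.subject_id in exclusions:
            continue
        for (condition, timepoint), rec in sorted(subj.recordings.items()):
            if channel_labels is None:
                channel_labels = tuple(rec.channel_labels)
            for i, seg in enumerate(segment_recording(rec, window)):
                samples.append(
                    Sample(
                        data=seg,
                        subject=subj.subject_id,
                        condition=condition,
                        timepoint=timepoint,
                        index=i,
                        label=subj.label,
                    )
                )
    if channel_labels is None:
        raise ValueError("no subjects left after exclusions")
    log.info(
        "assembled dataset: %d samples from %d subjects (%d excluded)",
        len(samples),
        len(known) - len(exclusions),
        len(exclusions),
    )
    return Dataset(samples=samples, channel_labels=channel_labels, exclusions=exclusions)
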