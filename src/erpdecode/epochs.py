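"""Epoched multichannel EEG container.

The :class:`EpochSet` is the currency passed between every stage of the
pipeline: a ``trials x channels x samples`` array in microvolts with a
per-trial class label (``standard`` / ``deviant``), a time axis in seconds
relative to stimulus onset, an ordered channel montage and a per-trial
recording-block index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Class label of the frequent tone.
STANDARD = "standard"
#: Class label of the rare (duration-deviant) tone.
DEVIANT = "deviant"

#: The reduced 10/20 montage usable on coma patients (frontal/central/
#: parietal/temporal rows), shared between patients and controls.
DEFAULT_MONTAGE = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "T7", "T8",
)


@dataclass
class EpochSet:
    """Epoched EEG trials with labels and montage metadata.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_samples)`` array, microvolts.
    labels:
        Per-trial class label, each ``"standard"`` or ``"deviant"``.
    times:
        Per-sample time in seconds relative to stimulus onset; strictly
        increasing with spacing ``1/sfreq``.
    sfreq:
        Sampling frequency in Hz.
    channels:
        Ordered channel names, one per data row.
    block_id:
        Per-trial recording-block index (1-based by convention).
    meta:
        Free-form provenance (subject id, session day, generator config...).
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: tuple[str, ...]
    block_id: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.channels = tuple(str(c) for c in self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n, c, s = self.data.shape
        if len(self.labels) != n or len(self.block_id) != n:
            raise ValueError("labels/block_id length must equal n_trials")
        if len(self.channels) != c:
            raise ValueError("channels length must equal data.shape[1]")
        if len(self.times) != s:
            raise ValueError("times length must equal data.shape[2]")
        bad = set(self.labels) - {STANDARD, DEVIANT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6):
            raise ValueError("times must increase with spacing 1/sfreq")

    # -- basic accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict[str, int]:
        """Number of trials per class label."""
        labs, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def y(self) -> np.ndarray:
        """Binary label vector: deviant = 1, standard = 0."""
        return (self.labels.astype(str) == DEVIANT).astype(int)

    # -- derived sets ----------------------------------------------------
    def select_trials(self, index: Sequence[int] | np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index].copy(),
            labels=self.labels[index].copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            channels=self.channels,
            block_id=self.block_id[index].copy(),
            meta=dict(self.meta),
        )

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        names = list(names)
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValueError(f"channels not in montage: {missing}")
        idx = [self.channels.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx].copy(),
            labels=self.labels.copy(),
            times=self.times.copy(),
            sfreq=self.sfreq,
            channels=tuple(names),
            block_id=self.block_id.copy(),
            meta=dict(self.meta),
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time axis to ``tmin <= t <= tmax``."""
        mask = (self.times >= tmin) & (self.times <= tmax)
        if not mask.any():
            raise ValueError("crop window contains no samples")
        return EpochSet(
            data=self.data[:, :, mask].copy(),
            labels=self.labels.copy(),
            times=self.times[mask].copy(),
            sfreq=self.sfreq,
            channels=self.channels,
            block_id=self.block_id.copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "EpochSet":
        return self.select_trials(np.arange(self.n_trials))

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        return (self.times >= start) & (self.times <= end)


def concatenate(blocks: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets trial-wise, preserving block order and block ids.

    All inputs must share montage, sampling rate and time axis.
    """
    if not blocks:
        raise ValueError("need at least one EpochSet")
    first = blocks[0]
    for b in blocks[1:]:
        if b.channels != first.channels:
            raise ValueError("montage mismatch between blocks")
        if b.sfreq != first.sfreq or not np.allclose(b.times, first.times):
            raise ValueError("time-axis mismatch between blocks")
    return EpochSet(
        data=np.concatenate([b.data for b in blocks], axis=0),
        labels=np.concatenate([b.labels for b in blocks]),
        times=first.times.copy(),
        sfreq=first.sfreq,
        channels=first.channels,
        block_id=np.concatenate([b.block_id for b in blocks]),
        meta={"n_blocks": len(blocks), **first.meta},
    )
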