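"""Offline conditioning chain for oddball EEG.

Stages, in the fixed pipeline order: zero-phase Butterworth band-pass plus
notch filtering, average-mastoid re-referencing, baseline correction,
amplitude-threshold artifact rejection, superblock concatenation and
undersampling class balance.  No stage alters the sampling rate, the time
axis, or the channel order (apart from dropping the mastoid channels at
re-referencing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .epochs import EpochSet, concatenate

#: Canonical stage order; assembled pipelines log their stages against it.
PIPELINE_ORDER = (
    "filter", "rereference", "baseline", "reject", "concatenate", "undersample",
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering/epoch-conditioning parameters.

    band
        Pass-band (low, high) in Hz; 0.1-30 Hz retains the slow MMN/P3a
        deflections while suppressing drift and line-frequency content.
    filter_order
        Butterworth order (applied forward-backward, i.e. zero phase, so
        the effective roll-off is doubled).
    notch
        Line-noise notch frequency in Hz, or ``None`` to skip.
    reject_threshold
        Absolute amplitude bound in microvolts; epochs with any value
        beyond +-threshold are discarded.
    baseline_window
        (start, end) seconds of the pre-stimulus interval whose mean is
        subtracted per trial and channel.
    reference
        Pair of mastoid channel names for average-mastoid re-referencing,
        or ``None`` when the data are already referenced.
    """

    band: tuple = (0.1, 30.0)
    filter_order: int = 4
    notch: float | None = 60.0
    reject_threshold: float = 75.0
    baseline_window: tuple = (-0.100, 0.0)
    reference: tuple | None = None

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 <= low < high):
            raise ValueError("band must satisfy 0 <= low < high")
        if self.reject_threshold <= 0:
            raise ValueError("reject_threshold must be > 0")


def bandpass_notch_filter(data: np.ndarray, sfreq: float,
                          cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass followed by a zero-phase notch.

    Operates on the last axis; accepts continuous ``(channels, samples)``
    arrays or epoched ``(trials, channels, samples)`` arrays.  Forward-
    backward application (``sosfiltfilt``) doubles the effective order and
    cancels the phase response.
    """
    cfg = cfg or PreprocessConfig()
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[-1]
    min_len = 3 * (2 * cfg.filter_order + 1)
    if n_samples <= min_len:
        raise ValueError(
            f"segment of {n_samples} samples is too short for zero-phase "
            f"order-{cfg.filter_order} filtering (need > {min_len})")
    low, high = cfg.band
    if high >= sfreq / 2:
        raise ValueError("band high edge must be below Nyquist")
    if low > 0:
        sos = sps.butter(cfg.filter_order, [low, high], btype="bandpass", fs=sfreq,
                         output="sos")
    else:
        sos = sps.butter(cfg.filter_order, high, btype="lowpass", fs=sfreq,
                         output="sos")
    out = sps.sosfiltfilt(sos, data, axis=-1)
    if cfg.notch is not None:
        if cfg.notch >= sfreq / 2:
            raise ValueError("notch frequency must be below Nyquist")
        b, a = sps.iirnotch(cfg.notch, Q=30.0, fs=sfreq)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def filter_epochs(e: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Apply :func:`bandpass_notch_filter` epoch-wise.

    Zero-phase IIR filtering on short epochs relies on the reflection
    padding built into ``sosfiltfilt``/``filtfilt``; prefer filtering the
    continuous recording when it is available.
    """
    out = e.copy()
    out.data = bandpass_notch_filter(e.data, e.sfreq, cfg)
    return out


def rereference(e: EpochSet, mastoids: Sequence[str] = ("M1", "M2")) -> EpochSet:
    """Subtract the average of the two mastoid channels, then drop them."""
    for ch in mastoids:
        if ch not in e.channels:
            raise ValueError(f"reference channel {ch!r} not in montage")
    m_idx = [e.channels.index(ch) for ch in mastoids]
    ref = e.data[:, m_idx].mean(axis=1, keepdims=True)
    keep = [i for i, ch in enumerate(e.channels) if ch not in mastoids]
    out = e.copy()
    out.data = e.data[:, keep] - ref
    out.channels = tuple(e.channels[i] for i in keep)
    return out


def baseline_correct(e: EpochSet,
                     window: tuple[float, float] = (-0.100, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the baseline window."""
    mask = e.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = e.copy()
    out.data = e.data - e.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(e: EpochSet, threshold: float = 75.0,
                     ) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere.

    Returns the cleaned set and the indices of the rejected trials.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peak = np.abs(e.data).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > threshold)
    if len(rejected) == e.n_trials:
        raise ValueError(
            f"all {e.n_trials} trials exceed +-{threshold} uV; nothing left")
    kept = np.setdiff1d(np.arange(e.n_trials), rejected)
    return e.select_trials(kept), rejected


def concatenate_superblock(blocks: Sequence[EpochSet]) -> EpochSet:
    """Concatenate recording blocks into one superblock (block ids kept)."""
    return concatenate(blocks)


def undersample_balance(e: EpochSet, seed: int | np.random.Generator = 0,
                        ) -> EpochSet:
    """Randomly subsample the majority class down to the minority count.

    Oddball designs are heavily unbalanced (standards outnumber deviants);
    balancing by undersampling prevents the classifier from exploiting the
    base rate.  Trial order is preserved among the retained trials.
    """
    counts = e.class_counts()
    if len(counts) < 2 or min(counts.values()) == 0:
        raise ValueError("both classes must be present to balance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(counts.items(), key=lambda kv: kv[1])
    minority, majority = ordered[0][0], ordered[1][0]
    if counts[minority] == counts[majority]:
        return e.copy()
    n_keep = counts[minority]
    maj_idx = np.flatnonzero(e.labels.astype(str) == majority)
    keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    min_idx = np.flatnonzero(e.labels.astype(str) == minority)
    keep = np.sort(np.concatenate([keep_maj, min_idx]))
    return e.select_trials(keep)


def preprocess_blocks(blocks: Sequence[EpochSet],
                      cfg: PreprocessConfig | None = None,
                      apply_filter: bool = True,
                      seed: int = 0,
                      ) -> tuple[EpochSet, list[dict]]:
    """Run the full chain on a list of blocks and return the balanced
    superblock plus a provenance trail (trial counts per stage).

    Order: filter -> re-reference -> baseline -> reject (per block), then
    concatenate -> undersample.  Rejection operates on filtered,
    baseline-corrected epochs.
    """
    cfg = cfg or PreprocessConfig()
    trail: list[dict] = []
    cleaned = []
    for b in blocks:
        e = b
        if apply_filter and cfg.band is not None:
            e = filter_epochs(e, cfg)
        if cfg.reference is not None:
            e = rereference(e, cfg.reference)
        e = baseline_correct(e, cfg.baseline_window)
        e, rejected = reject_artifacts(e, cfg.reject_threshold)
        trail.append({"stage": "block", "block": int(b.block_id[0]) if b.n_trials else -1,
                      "n_in": b.n_trials, "n_rejected": len(rejected),
                      "n_out": e.n_trials})
        cleaned.append(e)
    sb = concatenate_superblock(cleaned)
    trail.append({"stage": "concatenate", "n_out": sb.n_trials,
                  "counts": sb.class_counts()})
    sb = undersample_balance(sb, seed)
    trail.append({"stage": "undersample", "n_out": sb.n_trials,
                  "counts": sb.class_counts()})
    return sb, trail
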