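"""Reading and writing epoch data.

Two on-disk forms are supported:

* the package's own epoch container — a directory holding a raw
  little-endian float64 array (``data.bin``) and a JSON sidecar
  (``epochs.json``) with labels, time axis, montage, block ids and
  free-form metadata;
* standard continuous EEG files (EDF/BDF, BrainVision ``.vhdr``) read via
  MNE, epoched against a user-supplied event list with an
  event-code-to-class mapping.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .epochs import EpochSet

_SIDECAR = "epochs.json"
_ARRAY = "data.bin"


def save_epochs(e: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to a container directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    e.data.astype("<f8").tofile(path / _ARRAY)
    sidecar = {
        "shape": list(e.data.shape),
        "dtype": "<f8",
        "labels": e.labels.astype(str).tolist(),
        "times": e.times.tolist(),
        "sfreq": e.sfreq,
        "channels": list(e.channels),
        "block_id": e.block_id.tolist(),
        "meta": _jsonable(e.meta),
        "units": "microvolts",
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def load_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` back from a container directory."""
    path = Path(path)
    sidecar = json.loads((path / _SIDECAR).read_text())
    data = np.fromfile(path / _ARRAY, dtype=sidecar["dtype"])
    data = data.reshape(sidecar["shape"])
    return EpochSet(
        data=data,
        labels=np.asarray(sidecar["labels"], dtype=object),
        times=np.asarray(sidecar["times"]),
        sfreq=float(sidecar["sfreq"]),
        channels=tuple(sidecar["channels"]),
        block_id=np.asarray(sidecar["block_id"]),
        meta=sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_continuous(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Load a continuous EEG file (EDF/BDF/BrainVision) as microvolts.

    Returns ``(data (channels x samples, uV), sfreq, channel_names)``.
    """
    import mne  # deferred: slow import, only needed for real recordings

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported continuous format: {path.name}")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def epoch_continuous(data: np.ndarray, sfreq: float, channels: Sequence[str],
                     onsets: Sequence[int], codes: Sequence,
                     code_map: Mapping, window: tuple = (-0.100, 0.600),
                     block_id: Sequence[int] | None = None,
                     meta: dict | None = None) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    Parameters
    ----------
    onsets:
        Stimulus onsets in samples.
    codes:
        Event code per onset.
    code_map:
        Mapping from event code to class label (``standard``/``deviant``);
        onsets with unmapped codes are skipped.
    window:
        Epoch extent (start, end) seconds relative to onset, half-open on
        the right.
    """
    data = np.asarray(data, dtype=float)
    start, end = window
    n = int(round((end - start) * sfreq))
    offset = int(round(start * sfreq))
    times = start + np.arange(n) / sfreq
    epochs, labels, blocks = [], [], []
    for i, (onset, code) in enumerate(zip(onsets, codes)):
        if code not in code_map:
            continue
        lo = int(onset) + offset
        hi = lo + n
        if lo < 0 or hi > data.shape[1]:
            raise ValueError(f"event at sample {onset} falls outside the recording")
        epochs.append(data[:, lo:hi])
        labels.append(code_map[code])
        blocks.append(block_id[i] if block_id is not None else 1)
    if not epochs:
        raise ValueError("no events matched the code map")
    return EpochSet(
        data=np.stack(epochs),
        labels=np.asarray(labels, dtype=object),
        times=times,
        sfreq=sfreq,
        channels=tuple(channels),
        block_id=np.asarray(blocks),
        meta=meta or {},
    )
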