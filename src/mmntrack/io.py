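"""Reading and writing: fixture datasets, evoked tables, standard EEG formats.

A fixture dataset is a directory holding the epochs tensor as ``epochs.npy``
plus a JSON sidecar (``meta.json``) with channels, sampling rate, per-trial
labels, seeds and a config echo.  Round-trips are lossless.

EDF(+) and BrainVision recordings are ingested through mne's readers and
epoched in-package at event markers; only reading is supported.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EpochsSet, EvokedResponse
from .errors import ConfigurationError

FIXTURE_DATA = "epochs.npy"
FIXTURE_META = "meta.json"


def save_epochs(path: str | Path, epochs: EpochsSet, config_echo: dict | None = None) -> Path:
    """Write an EpochsSet as a fixture directory (tensor + JSON sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / FIXTURE_DATA, epochs.data)
    meta = {
        "channel_names": list(epochs.channel_names),
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "time_ms": epochs.time_ms.tolist(),
        "condition": [str(c) for c in epochs.condition],
        "block_id": [_jsonable(b) for b in epochs.block_id],
        "subject_id": epochs.subject_id,
        "rejected": epochs.rejected.astype(int).tolist(),
        "post_deviant": epochs.post_deviant.astype(int).tolist(),
        "meta": _jsonable(epochs.meta),
        "config_echo": _jsonable(config_echo) if config_echo is not None else None,
    }
    (path / FIXTURE_META).write_text(json.dumps(meta, indent=1))
    return path


def load_epochs(path: str | Path) -> EpochsSet:
    """Load a fixture directory written by :func:`save_epochs`."""
    path = Path(path)
    meta = json.loads((path / FIXTURE_META).read_text())
    data = np.load(path / FIXTURE_DATA)
    return EpochsSet(
        data=data,
        channel_names=meta["channel_names"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        time_ms=np.asarray(meta["time_ms"], dtype=float),
        condition=np.asarray(meta["condition"]),
        block_id=np.asarray(meta["block_id"], dtype=object),
        subject_id=meta["subject_id"],
        rejected=np.asarray(meta["rejected"], dtype=bool),
        post_deviant=np.asarray(meta["post_deviant"], dtype=bool),
        meta=meta.get("meta") or {},
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


# ---------------------------------------------------------------------------
# evoked / table export
# ---------------------------------------------------------------------------


def write_evoked_tsv(path: str | Path, evoked: EvokedResponse) -> Path:
    """Channel x time tab-separated export of one evoked response."""
    path = Path(path)
    df = pd.DataFrame(
        evoked.data, index=evoked.channel_names, columns=evoked.time_ms
    )
    df.index.name = "channel"
    df.to_csv(path, sep="\t")
    return path


def read_evoked_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="channel")


def write_intervals_bed(
    path: str | Path, intervals: Sequence[tuple[float, float]], name: str = "interval"
) -> Path:
    """Significant intervals as BED-like half-open [start_ms, end_ms) rows."""
    path = Path(path)
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{name}\t{start:.3f}\t{end:.3f}\n")
    return path


def read_manual_annotations(path: str | Path) -> pd.DataFrame:
    """Manual-visual annotations from CSV.

    Expected columns: subject_id, block, deviant, component, present,
    annotator (the annotator tag is mandatory for manual entries).
    """
    df = pd.read_csv(path)
    required = {"subject_id", "block", "deviant", "component", "present", "annotator"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"annotation file missing columns: {sorted(missing)}"
        )
    if df["annotator"].isna().any():
        raise ConfigurationError("manual-visual entries must carry an annotator tag")
    df["present"] = df["present"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# standard EEG formats (via mne)
# ---------------------------------------------------------------------------


def epochs_from_raw(
    raw,
    event_onsets_s: np.ndarray,
    event_conditions: Sequence[str],
    tmin_s: float = -0.1,
    tmax_s: float = 0.6,
    block_id: object = 1,
    subject_id: str = "S01",
    unit_scale: float = 1e6,
) -> EpochsSet:
    """Epoch an mne Raw object at the given onsets.

    ``unit_scale`` converts the raw's native unit to microvolts (mne raws
    are in volts, hence the default 1e6).  Events whose epoch would extend
    past the recording are dropped.
    """
    sfreq = float(raw.info["sfreq"])
    data = raw.get_data() * unit_scale  # (channels, samples)
    n_before = int(round(-tmin_s * sfreq))
    n_after = int(round(tmax_s * sfreq))
    time_ms = (np.arange(-n_before, n_after + 1) / sfreq) * 1000.0
    trials, kept = [], []
    for onset, cond in zip(np.asarray(event_onsets_s, dtype=float), event_conditions):
        center = int(round(onset * sfreq))
        lo, hi = center - n_before, center + n_after + 1
        if lo < 0 or hi > data.shape[1]:
            continue
        trials.append(data[:, lo:hi])
        kept.append(str(cond))
    if not trials:
        raise ConfigurationError("no events fit inside the recording")
    arr = np.stack(trials)
    return EpochsSet(
        data=arr,
        channel_names=list(raw.ch_names),
        sampling_rate_hz=sfreq,
        time_ms=time_ms,
        condition=np.asarray(kept),
        block_id=np.full(len(kept), block_id, dtype=object),
        subject_id=subject_id,
    )


def read_epochs_edf(
    path: str | Path,
    event_map: Mapping[str, str] | None = None,
    **kwargs,
) -> EpochsSet:
    """Read an EDF(+) file and epoch at its annotations.

    ``event_map`` maps annotation descriptions to condition names;
    unmapped annotations are skipped when a map is given.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _epochs_from_annotations(raw, event_map, **kwargs)


def read_epochs_brainvision(
    path: str | Path,
    event_map: Mapping[str, str] | None = None,
    **kwargs,
) -> EpochsSet:
    """Read a BrainVision (.vhdr) recording and epoch at its markers."""
    import mne

    raw = mne.io.read_raw_brainvision(str(path), preload=True, verbose="error")
    return _epochs_from_annotations(raw, event_map, **kwargs)


def _epochs_from_annotations(raw, event_map, **kwargs) -> EpochsSet:
    onsets, conds = [], []
    for ann in raw.annotations:
        desc = ann["description"]
        if event_map is not None:
            if desc not in event_map:
                continue
            desc = event_map[desc]
        onsets.append(ann["onset"])
        conds.append(desc)
    return epochs_from_raw(raw, np.asarray(onsets), conds, **kwargs)
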