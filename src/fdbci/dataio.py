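"""Containers and I/O for multichannel EEG trial data and result tables.

A :class:`TrialSet` holds one recording session's labelled trials as a
``(trials, channels, samples)`` array in microvolts together with its
sampling metadata.  Trial sets serialize to a single self-describing HDF5
file; result tables serialize to diff-able CSV.  Ingestion of GDF recordings
(the format used by public motor-imagery competition data) is available as
an optional extra and the rest of the package functions without it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialSet",
    "ResultTable",
    "save_trialset",
    "load_trialset",
    "epoch_from_events",
    "import_gdf",
]

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


@dataclass
class TrialSet:
    """Labelled multichannel EEG trials from one recording session.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial signals in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial (normalized to {0, 1} at import time).
    session_id : str
        Session token, e.g. ``"day1"`` or ``"day2"``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel names, one per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    session_id: str
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.data.shape[0] == 0:
            raise ValueError("data contains 0 trials; a TrialSet must hold at least one trial")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape[0] if self.labels.ndim == 1 else self.labels.shape} "
                f"does not match trial count {self.data.shape[0]}"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be a positive sampling rate in Hz; got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    # -- shape accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.fs

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def require_two_classes(self) -> None:
        """Raise unless exactly two distinct label values are present."""
        classes = self.classes
        if classes.size != 2:
            raise ValueError(
                f"labels must contain exactly two distinct classes; found {classes.tolist()}"
            )

    def with_data(self, data: np.ndarray, **overrides) -> "TrialSet":
        """Copy of this trial set with ``data`` (and metadata overrides) replaced."""
        kw = dict(
            labels=self.labels.copy(),
            session_id=self.session_id,
            fs=self.fs,
            channel_names=list(self.channel_names),
        )
        kw.update(overrides)
        return TrialSet(data=data, **kw)


def save_trialset(ts: TrialSet, path: str | Path) -> None:
    """Write a :class:`TrialSet` to a self-describing HDF5 file.

    The round trip through :func:`load_trialset` is bit-exact for the data
    array and exact for all metadata.
    """
    import h5py

    ts.require_two_classes()
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "fdbci-trialset"
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["session_id"] = ts.session_id
        f.attrs["fs"] = float(ts.fs)
        f.attrs["channel_names"] = [str(c) for c in ts.channel_names]
        f.create_dataset("data", data=ts.data)
        f.create_dataset("labels", data=ts.labels)


def load_trialset(path: str | Path) -> TrialSet:
    """Read a :class:`TrialSet` written by :func:`save_trialset`.

    Raises a descriptive error naming the offending field on schema
    mismatch or corrupted dimensions.
    """
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open trial-set file {path!r}: {exc}") from exc
    with f:
        if f.attrs.get("format") != "fdbci-trialset":
            raise ValueError(f"{path!r}: missing or wrong 'format' attribute; not a trial-set file")
        for key in ("data", "labels"):
            if key not in f:
                raise ValueError(f"{path!r}: required dataset '{key}' is absent")
        for key in ("session_id", "fs", "channel_names"):
            if key not in f.attrs:
                raise ValueError(f"{path!r}: required attribute '{key}' is absent")
        data = f["data"][()]
        labels = f["labels"][()]
        try:
            return TrialSet(
                data=data,
                labels=labels,
                session_id=str(f.attrs["session_id"]),
                fs=float(f.attrs["fs"]),
                channel_names=[str(c) for c in f.attrs["channel_names"]],
            )
        except ValueError as exc:
            raise ValueError(f"{path!r}: corrupted trial set: {exc}") from exc


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = ["subject", "technique", "condition", "f_low", "width", "mean_acc", "std_acc"]


class ResultTable:
    """Per-(subject, technique, condition, band) accuracy table.

    Each row stores the repetition accuracies of one resampled evaluation
    together with their mean and standard deviation, mirroring the layout of
    published per-subject accuracy tables.  The summary CSV uses the header
    ``subject,technique,condition,f_low,width,mean_acc,std_acc``; repetition
    accuracies are kept in ``rep_*`` columns of the full frame.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self.validate()

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "ResultTable":
        """Build from dicts with keys subject/technique/condition/f_low/width/accuracies."""
        records = []
        for row in rows:
            acc = np.asarray(row["accuracies"], dtype=np.float64)
            rec = {
                "subject": row["subject"],
                "technique": row["technique"],
                "condition": row["condition"],
                "f_low": int(row["f_low"]),
                "width": int(row["width"]),
                "mean_acc": float(acc.mean()),
                "std_acc": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
            }
            rec.update({f"rep_{i:02d}": float(a) for i, a in enumerate(acc)})
            records.append(rec)
        return cls(pd.DataFrame.from_records(records))

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("rep_")]

    def validate(self) -> None:
        missing = [c for c in _SUMMARY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"result table lacks required columns {missing}")
        reps = self.frame[self.rep_columns].to_numpy(dtype=np.float64)
        if reps.size:
            if np.nanmin(reps) < 0.0 or np.nanmax(reps) > 1.0:
                raise ValueError("repetition accuracies must lie in [0, 1]")
            recomputed = np.nanmean(reps, axis=1)
            if not np.allclose(recomputed, self.frame["mean_acc"].to_numpy(), atol=1e-12, rtol=0):
                raise ValueError("mean_acc inconsistent with stored repetition accuracies")
        if ((self.frame["mean_acc"] < 0) | (self.frame["mean_acc"] > 1)).any():
            raise ValueError("mean_acc must lie in [0, 1]")

    def to_csv(self, path: str | Path, *, repetitions: bool = False) -> None:
        """Write the summary (or, with ``repetitions=True``, the full) table."""
        cols = _SUMMARY_COLUMNS + (self.rep_columns if repetitions else [])
        self.frame[cols].to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResultTable":
        frame = pd.read_csv(path)
        if not set(c for c in frame.columns if c.startswith("rep_")):
            # summary-only file: treat the stored mean as a single repetition
            frame = frame.assign(rep_00=frame["mean_acc"])
        return cls(frame)


# ---------------------------------------------------------------------------
# epoching and optional GDF ingestion
# ---------------------------------------------------------------------------


def epoch_from_events(
    signals: np.ndarray,
    events: Sequence[tuple[int, object]],
    fs: float,
    class_pair: tuple[object, object],
    *,
    trial_seconds: float = 3.0,
    session_id: str = "day1",
    channel_names: Sequence[str] | None = None,
) -> TrialSet:
    """Cut fixed-length trials out of a continuous multichannel recording.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_total_samples)
        Continuous recording.
    events : sequence of (sample_index, code)
        Cue-onset markers; only events whose code is in ``class_pair`` become
        trials.  The two requested codes map to labels 0 and 1 in order.
    class_pair : pair of codes
        The two task codes to keep.
    trial_seconds : float
        Trial length cut from each onset (3 s for the motor-imagery task
        period of the competition recordings).

    Trials whose ``trial_seconds`` span runs past the end of the recording
    are dropped with a logged warning reporting the count.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError(f"signals must be 2-D (channels, samples); got shape {signals.shape}")
    if len(class_pair) != 2 or class_pair[0] == class_pair[1]:
        raise ValueError("class_pair must name two distinct class codes")
    available = sorted({str(code) for _, code in events})
    for code in class_pair:
        if str(code) not in available:
            raise ValueError(
                f"class code {code!r} not present in the recording; available codes: {available}"
            )
    n_len = int(round(trial_seconds * fs))
    label_of = {str(class_pair[0]): 0, str(class_pair[1]): 1}
    trials, labels, dropped = [], [], 0
    for onset, code in events:
        if str(code) not in label_of:
            continue
        onset = int(onset)
        if onset < 0 or onset + n_len > signals.shape[1]:
            dropped += 1
            continue
        trials.append(signals[:, onset : onset + n_len])
        labels.append(label_of[str(code)])
    if dropped:
        msg = f"dropped {dropped} trial(s) shorter than {trial_seconds} s after the cue"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not trials:
        raise ValueError("no complete trials found for the requested class codes")
    return TrialSet(
        data=np.stack(trials),
        labels=np.asarray(labels),
        session_id=session_id,
        fs=fs,
        channel_names=list(channel_names) if channel_names is not None else [],
    )


# cue codes used by the motor-imagery competition GDF recordings
GDF_CLASS_CODES = {"left": "769", "right": "770", "feet": "771", "tongue": "772"}


def import_gdf(
    path: str | Path,
    class_pair: tuple[str, str],
    *,
    trial_seconds: float = 3.0,
    session_id: str | None = None,
) -> TrialSet:
    """Read one session of a GDF motor-imagery recording into a :class:`TrialSet`.

    ``class_pair`` names two tasks out of ``left``/``right``/``feet``/``tongue``
    (or gives raw event codes directly).  Requires the optional ``mne``
    backend; without it a descriptive "external-data feature unavailable"
    error is raised and the rest of the package is unaffected.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise RuntimeError(
            "external-data feature unavailable: GDF ingestion needs the optional "
            "'mne' dependency (pip install fdbci[gdf])"
        ) from exc

    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    idx_to_desc = {int(idx): desc for desc, idx in event_id.items()}
    requested = [GDF_CLASS_CODES.get(c, c) for c in class_pair]
    ev = [(int(s), idx_to_desc[int(i)]) for s, _, i in events if int(i) in idx_to_desc]
    eeg_picks = mne.pick_types(raw.info, eeg=True)
    signals = raw.get_data(picks=eeg_picks) * 1e6  # volts -> microvolts
    names = [raw.ch_names[i] for i in eeg_picks]
    return epoch_from_events(
        signals,
        ev,
        fs=float(raw.info["sfreq"]),
        class_pair=(requested[0], requested[1]),
        trial_seconds=trial_seconds,
        session_id=session_id or Path(path).stem,
        channel_names=names,
    )
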