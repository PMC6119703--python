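"""Session containers, event tables, trial extraction, and movement-onset detection.

A session couples a continuous multichannel cortical recording with a data-glove
flexion trace and an event table holding, per trial, the gesture-cue start, the
detected hand-motion onset, and the gesture-cue stop.  Decoding epochs are cut
between motion onset and cue stop.  Sessions round-trip through an HDF5
container (groups ``/ecog``, ``/glove``, ``/events``); event tables also export
to TSV.

All timestamps are in seconds and refer to sample-start boundaries; signals are
indexed 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("cue_start", "cue_stop", "onset")

EVENT_COLUMNS = ("trial_id", "kind", "timestamp_s", "label")


class FormatError(ValueError):
    """A session container is missing a required group, dataset or attribute."""


@dataclass
class EventTable:
    """Rows of (trial_id, kind, timestamp_s, label).

    ``kind`` is drawn from :data:`EVENT_KINDS`; ``label`` is the gesture class
    (kept on the ``cue_start`` row, empty string elsewhere).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        bad = set(self.frame["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)
        for tid, rows in self.frame.groupby("trial_id"):
            times = {r.kind: r.timestamp_s for r in rows.itertuples()}
            if {"cue_start", "cue_stop", "onset"} <= times.keys():
                if not times["cue_start"] < times["onset"] < times["cue_stop"]:
                    raise ValueError(
                        f"trial {tid}: require cue_start < onset < cue_stop, "
                        f"got {times}"
                    )
            elif {"cue_start", "cue_stop"} <= times.keys():
                if not times["cue_start"] < times["cue_stop"]:
                    raise ValueError(f"trial {tid}: cue_start >= cue_stop")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "EventTable":
        return cls(pd.DataFrame(list(rows), columns=list(EVENT_COLUMNS)))

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.frame["trial_id"].unique())

    def times_for(self, trial_id: int) -> dict[str, float]:
        rows = self.frame[self.frame["trial_id"] == trial_id]
        return dict(zip(rows["kind"], rows["timestamp_s"]))

    def label_for(self, trial_id: int):
        rows = self.frame[
            (self.frame["trial_id"] == trial_id) & (self.frame["kind"] == "cue_start")
        ]
        if rows.empty:
            return None
        return rows["label"].iloc[0]

    def max_time(self) -> float:
        return float(self.frame["timestamp_s"].max())

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["timestamp_s"] = out["timestamp_s"].map(lambda t: f"{t:.6f}")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        frame = pd.read_csv(path, sep="\t", dtype={"label": str}, keep_default_na=False)
        frame["timestamp_s"] = frame["timestamp_s"].astype(float)
        return cls(frame)


@dataclass
class Recording:
    """Continuous multichannel recording (channels x samples) with events."""

    signal: np.ndarray
    fs: float
    channel_ids: list[str]
    events: EventTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        if self.events is not None:
            dur = self.signal.shape[1] / self.fs
            ts = self.events.frame["timestamp_s"]
            if (ts < 0).any() or (ts > dur).any():
                raise ValueError(
                    f"event timestamps outside [0, {dur:.6f}] s recording span"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GloveRecording:
    """Data-glove flexion traces (sensors x samples), normalized flexion units."""

    flexion: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.flexion = np.asarray(self.flexion, dtype=np.float64)
        if self.flexion.ndim != 2:
            raise ValueError("flexion must be sensors x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_sensors(self) -> int:
        return self.flexion.shape[0]

    @property
    def n_samples(self) -> int:
        return self.flexion.shape[1]


@dataclass
class TrialEpoch:
    """Per-trial signal slice anchored at movement onset, with gesture label."""

    signal: np.ndarray  # channels x samples, sliced [onset, cue_stop)
    label: object
    t0: float  # onset timestamp, seconds
    span: tuple[float, float]  # (onset, cue_stop) in seconds
    fs: float
    trial_id: int = -1

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("epoch span must have positive length")

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


def detect_onset(
    glove: GloveRecording,
    threshold: float,
    search_window: tuple[float, float] | None = None,
    min_run: int = 5,
    smooth_samples: int = 0,
) -> float | None:
    """Detect the movement onset from glove flexion derivatives.

    The onset is the time of the FIRST sample of the earliest run (across all
    sensors) of at least ``min_run`` consecutive first-difference values
    exceeding ``threshold``.  The first difference ``x[i+1] - x[i]`` is
    attributed to sample ``i+1`` (the first sample that has already moved).
    Returns ``None`` when no qualifying run exists.

    ``smooth_samples`` optionally applies a moving-average pre-filter of that
    length to the flexion traces before differencing (off by default).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.isfinite(glove.flexion).all():
        raise ValueError("glove flexion contains non-finite values")
    x = glove.flexion
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        x = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 1, x)
    d = np.diff(x, axis=1)  # d[:, i] enters sample i+1
    lo, hi = 0, d.shape[1]
    if search_window is not None:
        t0, t1 = search_window
        if not (0 <= t0 < t1 <= glove.n_samples / glove.fs):
            raise ValueError("search window outside the recording")
        lo = max(lo, int(np.floor(t0 * glove.fs)))
        hi = min(hi, int(np.ceil(t1 * glove.fs)))
        if hi <= lo:
            raise ValueError("empty search window")
    supra = (d[:, lo:hi] > threshold).astype(np.int64)
    if supra.shape[1] < min_run:
        return None
    csum = np.concatenate(
        [np.zeros((supra.shape[0], 1), dtype=np.int64), np.cumsum(supra, axis=1)],
        axis=1,
    )
    full_run = (csum[:, min_run:] - csum[:, :-min_run]) == min_run
    starts = np.argwhere(full_run)
    if starts.size == 0:
        return None
    best = lo + int(starts[:, 1].min())
    return (best + 1) / glove.fs


def extract_trials(
    rec: Recording,
    onsets: Mapping[int, float],
) -> list[TrialEpoch]:
    """Cut one epoch per valid trial, sliced [onset, cue_stop).

    Trials with no detected onset (absent from ``onsets`` or mapped to None)
    are dropped and counted in the log; an onset at or after cue_stop marks
    the trial invalid and it is likewise excluded.
    """
    epochs: list[TrialEpoch] = []
    n_dropped = 0
    for tid in rec.events.trial_ids:
        times = rec.events.times_for(tid)
        if "cue_start" not in times or "cue_stop" not in times:
            n_dropped += 1
            continue
        onset = onsets.get(tid)
        if onset is None:
            n_dropped += 1
            continue
        if onset >= times["cue_stop"]:
            logger.warning("trial %d: onset %.3f s >= cue_stop, excluded", tid, onset)
            n_dropped += 1
            continue
        i0 = int(round(onset * rec.fs))
        i1 = int(round(times["cue_stop"] * rec.fs))
        epochs.append(
            TrialEpoch(
                signal=rec.signal[:, i0:i1],
                label=rec.events.label_for(tid),
                t0=onset,
                span=(onset, times["cue_stop"]),
                fs=rec.fs,
                trial_id=tid,
            )
        )
    if n_dropped:
        logger.info("extract_trials: dropped %d invalid trial(s)", n_dropped)
    return epochs


def detect_trial_onsets(
    events: EventTable,
    glove: GloveRecording,
    threshold: float,
    min_run: int = 5,
) -> dict[int, float | None]:
    """Detect one onset per trial, searching [cue_start, cue_stop)."""
    out: dict[int, float | None] = {}
    for tid in events.trial_ids:
        times = events.times_for(tid)
        if "cue_start" not in times or "cue_stop" not in times:
            out[tid] = None
            continue
        out[tid] = detect_onset(
            glove, threshold, (times["cue_start"], times["cue_stop"]), min_run
        )
    return out


def relax_intervals(events: EventTable, duration: float) -> list[tuple[float, float]]:
    """Per trial, the relax interval preceding its cue: [previous cue_stop, cue_start)."""
    out = []
    prev_stop = 0.0
    for tid in events.trial_ids:
        times = events.times_for(tid)
        if "cue_start" not in times:
            continue
        start = prev_stop
        stop = times["cue_start"]
        if stop > start:
            out.append((start, stop))
        prev_stop = times.get("cue_stop", stop)
    return out


def write_session(rec: Recording, glove: GloveRecording | None, path) -> None:
    """Write a session container: /ecog, /glove, /events groups in HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("ecog")
        g.create_dataset("signal", data=rec.signal)
        g.attrs["fs"] = rec.fs
        g.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        if glove is not None:
            gg = f.create_group("glove")
            gg.create_dataset("flexion", data=glove.flexion)
            gg.attrs["fs"] = glove.fs
        ev = f.create_group("events")
        frame = rec.events.frame
        ev.create_dataset("trial_id", data=frame["trial_id"].to_numpy(dtype=np.int64))
        ev.create_dataset(
            "kind", data=np.array(frame["kind"], dtype=h5py.string_dtype())
        )
        ev.create_dataset("timestamp_s", data=frame["timestamp_s"].to_numpy(float))
        ev.create_dataset(
            "label",
            data=np.array([str(v) for v in frame["label"]], dtype=h5py.string_dtype()),
        )


def read_session(path) -> tuple[Recording, GloveRecording | None]:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if "ecog" not in f:
            raise FormatError("missing /ecog group")
        g = f["ecog"]
        if "signal" not in g:
            raise FormatError("missing /ecog/signal dataset")
        if "fs" not in g.attrs:
            raise FormatError("missing /ecog fs attribute")
        if "events" not in f:
            raise FormatError("missing /events group")
        ev = f["events"]
        for name in ("trial_id", "kind", "timestamp_s", "label"):
            if name not in ev:
                raise FormatError(f"missing /events/{name} dataset")
        frame = pd.DataFrame(
            {
                "trial_id": ev["trial_id"][()].astype(int),
                "kind": [s.decode() for s in ev["kind"][()]],
                "timestamp_s": ev["timestamp_s"][()].astype(float),
                "label": [s.decode() for s in ev["label"][()]],
            }
        )
        rec = Recording(
            signal=g["signal"][()],
            fs=float(g.attrs["fs"]),
            channel_ids=[str(c) for c in g.attrs["channel_ids"]],
            events=EventTable(frame),
        )
        glove = None
        if "glove" in f:
            glove = GloveRecording(
                flexion=f["glove"]["flexion"][()], fs=float(f["glove"].attrs["fs"])
            )
    return rec, glove
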