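"""Core in-memory containers: multichannel recordings and trial schedules.

Amplitudes are microvolts throughout (MEP tables convert to millivolts at
the reporting layer). Time is seconds from recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = ["Recording", "Trial", "TrialSchedule"]


@dataclass
class Recording:
    """A multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    srate : float
        Sampling rate in samples per second.
    labels : list of str
        Channel names, one per row of ``data``.
    start_time : float
        Time of the first sample in seconds.
    meta : dict
        Free-form metadata; generators store ground truth here.
    """

    data: np.ndarray
    srate: float
    labels: list[str]
    start_time: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.srate <= 0:
            raise ValueError(f"srate must be positive, got {self.srate}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.srate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by name."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording "
                           f"(have {self.labels})") from None
        return self.data[idx]

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` in the given order."""
        rows = np.array([self.labels.index(l) for l in self._check(labels)])
        return Recording(self.data[rows].copy(), self.srate, list(labels),
                         self.start_time, dict(self.meta))

    def drop(self, labels: Sequence[str]) -> "Recording":
        keep = [l for l in self.labels if l not in set(labels)]
        return self.pick(keep)

    def _check(self, labels: Sequence[str]) -> Sequence[str]:
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return labels

    def time_to_sample(self, t: float) -> int:
        return int(round((t - self.start_time) * self.srate))

    def crop(self, tmin: float, tmax: float) -> "Recording":
        """Samples in [tmin, tmax); raises if the span exceeds the recording."""
        i0, i1 = self.time_to_sample(tmin), self.time_to_sample(tmax)
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"crop [{tmin}, {tmax}) s outside recording of "
                f"{self.duration:.3f} s starting at {self.start_time} s")
        return Recording(self.data[:, i0:i1].copy(), self.srate,
                         list(self.labels), tmin, dict(self.meta))

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.srate, list(self.labels),
                         self.start_time, dict(self.meta))

    # -- columnar CSV interchange -------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as columnar CSV (time + one column per channel) with a
        ground-truth/metadata sidecar JSON next to it."""
        path = Path(path)
        df = pd.DataFrame(self.data.T, columns=self.labels)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False, float_format="%.6g")
        sidecar = {"srate": self.srate, "labels": self.labels,
                   "start_time": self.start_time, "meta": _jsonable(self.meta)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            srate, meta = sidecar["srate"], sidecar.get("meta", {})
            start = sidecar.get("start_time", 0.0)
        else:
            dt = np.diff(df["time"].to_numpy()[:2])[0]
            srate, meta, start = 1.0 / dt, {}, float(df["time"].iloc[0])
        labels = [c for c in df.columns if c != "time"]
        return cls(df[labels].to_numpy().T, srate, labels, start, meta)


@dataclass(frozen=True)
class Trial:
    """Epoch boundaries of one trial, in seconds."""

    rest_onset: float
    ready_onset: float
    imagery_onset: float
    imagery_end: float

    def __post_init__(self) -> None:
        seq = (self.rest_onset, self.ready_onset,
               self.imagery_onset, self.imagery_end)
        if not all(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"trial epochs must be strictly increasing: {seq}")


@dataclass
class TrialSchedule:
    """Rest / ready / imagery epoch boundaries for a block of trials.

    Defaults follow the standard block structure: 6 s rest, 1 s ready,
    5 s motor imagery per trial.
    """

    trials: list[Trial]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.trials, self.trials[1:]):
            if cur.rest_onset < prev.imagery_end:
                raise ValueError("trials overlap or are out of order")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def end_time(self) -> float:
        return self.trials[-1].imagery_end if self.trials else 0.0

    @classmethod
    def standard(cls, n_trials: int, rest: float = 6.0, ready: float = 1.0,
                 imagery: float = 5.0, iti: float = 0.0,
                 t0: float = 0.0) -> "TrialSchedule":
        trials = []
        t = t0
        for _ in range(n_trials):
            trials.append(Trial(t, t + rest, t + rest + ready,
                                t + rest + ready + imagery))
            t += rest + ready + imagery + iti
        return cls(trials)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([vars(t) for t in self.trials]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSchedule":
        df = pd.read_csv(path)
        return cls([Trial(r.rest_onset, r.ready_onset, r.imagery_onset,
                          r.imagery_end) for r in df.itertuples()])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
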