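"""Reaction-time extraction from surface EMG.

Onset rule: the trace is band-pass filtered (acquisition band, 10–500 Hz)
and rectified; the detection threshold is four times the standard deviation
of the rectified baseline immediately preceding the go cue. The EMG onset is
the first post-go sample that exceeds the threshold and whose following
10 ms of rectified signal stays above it on average (a debounce that
suppresses isolated noise crossings; set ``sustain=0`` for the literal
first-crossing rule). Trials with pre-cue EMG potentiation are flagged and
excluded from the session mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Recording

__all__ = ["OnsetConfig", "RtTrial", "preprocess_emg", "detect_onset",
           "reject_precue", "analyze_trial", "session_rt", "pre_rt_times"]


@dataclass
class OnsetConfig:
    threshold_factor: float = 4.0
    baseline_window: float = 0.5     # s immediately before go, for the SD
    sustain: float = 0.010           # s the signal must stay above threshold
    inspect_window: float = 1.0      # s before go screened for pre-cue bursts
    reference_window: float = 0.5    # s of quiet reference preceding inspect
    bandpass: tuple[float, float] = (10.0, 500.0)
    bp_order: int = 2
    max_rt: float = 1.0              # s, end of the onset search


@dataclass
class RtTrial:
    go_time: float
    onset_time: float | None
    rt: float | None
    rejected: bool = False
    reason: str = ""


def preprocess_emg(rec: Recording, cfg: OnsetConfig | None = None) -> Recording:
    """Causal acquisition-band filtering of the raw EMG."""
    cfg = cfg or OnsetConfig()
    hi = min(cfg.bandpass[1], 0.45 * rec.srate)
    sos = signal.butter(cfg.bp_order, (cfg.bandpass[0], hi), btype="bandpass",
                        fs=rec.srate, output="sos")
    data = signal.sosfilt(sos, rec.data, axis=1)
    return Recording(data, rec.srate, list(rec.labels), rec.start_time,
                     dict(rec.meta))


def _rectified(rec: Recording, cfg: OnsetConfig) -> np.ndarray:
    return np.abs(preprocess_emg(rec, cfg).data[0])


def _sustained_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Forward moving average: out[i] = mean(x[i : i+n])."""
    if n <= 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(len(x), np.nan)
    valid = len(x) - n + 1
    if valid > 0:
        out[:valid] = (c[n:] - c[:-n]) / n
    return out


def detect_onset(rec: Recording, go_time: float,
                 cfg: OnsetConfig | None = None,
                 rect: np.ndarray | None = None) -> float | None:
    """EMG burst onset after the go cue, or None if no burst is found."""
    cfg = cfg or OnsetConfig()
    rect = _rectified(rec, cfg) if rect is None else rect
    sr = rec.srate
    go_i = rec.time_to_sample(go_time)
    b0 = go_i - int(round(cfg.baseline_window * sr))
    if b0 < 0 or go_i >= len(rect):
        raise ValueError("baseline window falls outside the trace")
    if cfg.threshold_factor == 0:
        return go_time  # degenerate limit: every sample crosses
    threshold = cfg.threshold_factor * rect[b0:go_i].std()
    end_i = min(len(rect), go_i + int(round(cfg.max_rt * sr)))
    seg = rect[go_i:end_i]
    n_sus = max(1, int(round(cfg.sustain * sr)))
    above = seg > threshold
    sustained = _sustained_mean(seg, n_sus) > threshold
    hits = np.flatnonzero(above & sustained)
    if hits.size == 0:
        return None
    return go_time + hits[0] / sr


def reject_precue(rec: Recording, go_time: float,
                  cfg: OnsetConfig | None = None,
                  rect: np.ndarray | None = None) -> bool:
    """True if EMG potentiation is apparent in the pre-go inspection window.

    The threshold (4 × SD) comes from an earlier quiet reference segment so
    a pre-cue burst cannot inflate its own criterion.
    """
    cfg = cfg or OnsetConfig()
    rect = _rectified(rec, cfg) if rect is None else rect
    sr = rec.srate
    go_i = rec.time_to_sample(go_time)
    ref_n = int(round(cfg.reference_window * sr))
    # shrink the inspection window if the trace starts late, but always keep
    # a clean reference segment before it
    i0 = max(go_i - int(round(cfg.inspect_window * sr)), ref_n)
    r0 = i0 - ref_n
    if r0 < 0 or i0 >= go_i:
        raise ValueError("reference window falls outside the trace")
    threshold = cfg.threshold_factor * rect[r0:i0].std()
    n_sus = max(1, int(round(cfg.sustain * sr)))
    seg = rect[i0:go_i]
    flagged = (seg > threshold) & (_sustained_mean(seg, n_sus) > threshold)
    return bool(flagged.any())


def analyze_trial(rec: Recording, go_time: float,
                  cfg: OnsetConfig | None = None) -> RtTrial:
    cfg = cfg or OnsetConfig()
    rect = _rectified(rec, cfg)
    if reject_precue(rec, go_time, cfg, rect):
        return RtTrial(go_time, None, None, True, "pre-cue EMG potentiation")
    onset = detect_onset(rec, go_time, cfg, rect)
    if onset is None:
        return RtTrial(go_time, None, None, True, "no EMG burst detected")
    return RtTrial(go_time, onset, onset - go_time)


def session_rt(trials: list[RtTrial]) -> tuple[float, pd.DataFrame]:
    """Mean RT over accepted trials plus the per-trial table."""
    table = pd.DataFrame([vars(t) for t in trials])
    accepted = table.loc[~table["rejected"], "rt"]
    if accepted.empty:
        raise ValueError("no accepted trials in the session")
    return float(accepted.mean()), table


def pre_rt_times(baseline_rt: float,
                 fractions: tuple[float, ...] = (0.5, 0.8)) -> dict[float, float]:
    """Stimulus offsets after go for pre-RT probes (fraction × baseline RT)."""
    if baseline_rt <= 0:
        raise ValueError("baseline RT must be positive")
    return {f: f * baseline_rt for f in fractions}
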