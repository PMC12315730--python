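"""MEP quantification and short-interval intracortical inhibition (SICI).

Sweeps are band-pass filtered 10–450 Hz with a 50 Hz notch (fourth-order
Butterworth, zero-phase), segmented −100 to +150 ms around the stimulus,
and quantified as peak-to-peak amplitude inside a post-stimulus search
window. Per (protocol, condition) cell means feed the SICI ratio:

    SICI % = mean paired-pulse MEP / mean single-pulse MEP × 100

so lower percentages mean stronger inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Recording

__all__ = ["MepSegment", "SiciResult", "preprocess_mep", "segment_mep",
           "peak_to_peak", "condition_means", "sici", "analyze_sweeps"]

SEGMENT_WINDOW = (-0.100, 0.150)     # s around the stimulus
SEARCH_WINDOW = (0.015, 0.060)       # s post-stimulus for the peak-to-peak

PROTOCOLS = ("single", "paired")
CONDITIONS = ("rest", "rt50", "rt80")


@dataclass
class MepSegment:
    """Filtered sweep segment around one stimulus; amplitudes in µV."""

    trace: np.ndarray
    times: np.ndarray                # s relative to the stimulus
    srate: float
    protocol: str = "single"
    condition: str = "rest"

    @property
    def ptp_mv(self) -> float:
        return peak_to_peak(self)


@dataclass
class SiciResult:
    condition: str
    mean_single: float               # mV
    mean_paired: float               # mV
    sici_percent: float


def preprocess_mep(rec: Recording, band: tuple[float, float] = (10.0, 450.0),
                   notch_freq: float = 50.0, notch_q: float = 30.0,
                   order: int = 4, blank_stim: float | None = None,
                   stim_time: float | None = None) -> Recording:
    """Zero-phase band-pass + notch; optional stimulus-artifact blanking
    (±``blank_stim`` s around ``stim_time`` zeroed before filtering)."""
    if rec.srate < 1000:
        raise ValueError("MEP analysis expects >= 1 kHz sampling")
    data = rec.data.copy()
    if blank_stim and stim_time is not None:
        i0 = max(0, rec.time_to_sample(stim_time - blank_stim))
        i1 = min(rec.n_samples, rec.time_to_sample(stim_time + blank_stim))
        data[:, i0:i1] = 0.0
    sos = signal.butter(order, band, btype="bandpass", fs=rec.srate,
                        output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    b, a = signal.iirnotch(notch_freq, notch_q, fs=rec.srate)
    data = signal.filtfilt(b, a, data, axis=1)
    return Recording(data, rec.srate, list(rec.labels), rec.start_time,
                     dict(rec.meta))


def segment_mep(rec: Recording, stim_time: float, protocol: str = "single",
                condition: str = "rest",
                window: tuple[float, float] = SEGMENT_WINDOW) -> MepSegment:
    """Cut the −100..+150 ms segment around the stimulus."""
    i0 = rec.time_to_sample(stim_time + window[0])
    i1 = rec.time_to_sample(stim_time + window[1])
    if i0 < 0 or i1 > rec.n_samples:
        raise ValueError(
            f"segment {window} s around stimulus at {stim_time} s exceeds "
            "the sweep")
    times = (np.arange(i0, i1) / rec.srate + rec.start_time) - stim_time
    return MepSegment(rec.data[0, i0:i1].copy(), times, rec.srate,
                      protocol, condition)


def peak_to_peak(seg: MepSegment,
                 search_window: tuple[float, float] = SEARCH_WINDOW) -> float:
    """Max − min (mV) of the segment inside the post-stimulus search window."""
    m = (seg.times >= search_window[0]) & (seg.times <= search_window[1])
    if not m.any():
        raise ValueError(f"search window {search_window} outside the segment")
    x = seg.trace[m]
    return float((x.max() - x.min()) / 1000.0)   # µV → mV


def condition_means(segments: list[MepSegment],
                    search_window: tuple[float, float] = SEARCH_WINDOW
                    ) -> pd.DataFrame:
    """Mean peak-to-peak per (protocol, condition) cell."""
    rows = [{"protocol": s.protocol, "condition": s.condition,
             "ptp_mv": peak_to_peak(s, search_window)} for s in segments]
    table = pd.DataFrame(rows)
    return (table.groupby(["protocol", "condition"], as_index=False)
            .agg(mean_ptp_mv=("ptp_mv", "mean"), n=("ptp_mv", "size")))


def sici(means: pd.DataFrame) -> list[SiciResult]:
    """SICI percentage per condition from the cell-mean table."""
    out = []
    for condition in means["condition"].unique():
        sub = means[means["condition"] == condition]
        cells = dict(zip(sub["protocol"], sub["mean_ptp_mv"]))
        missing = [p for p in PROTOCOLS if p not in cells]
        if missing:
            raise ValueError(
                f"condition {condition!r} missing protocol cell(s): {missing}")
        out.append(SiciResult(condition, cells["single"], cells["paired"],
                              cells["paired"] / cells["single"] * 100.0))
    return out


def analyze_sweeps(sweeps: list[tuple[str, str, Recording]],
                   stim_time: float | None = None,
                   search_window: tuple[float, float] = SEARCH_WINDOW
                   ) -> tuple[pd.DataFrame, list[SiciResult]]:
    """Full MEP pipeline over (protocol, condition, sweep) triples.

    ``stim_time`` defaults to each sweep's recorded stimulus time.
    """
    segments = []
    for protocol, condition, rec in sweeps:
        t_stim = stim_time if stim_time is not None else rec.meta["stim_time"]
        filt = preprocess_mep(rec)
        segments.append(segment_mep(filt, t_stim, protocol, condition))
    means = condition_means(segments, search_window)
    return means, sici(means)
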