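"""Causal (real-time-equivalent) SMR-ERD feedback scoring.

The online chain mirrors a closed-loop neurofeedback system: a large
Laplacian over the target electrode, a causal 1–70 Hz Butterworth band-pass
with a 50 Hz notch, a trailing 1-s Hann-tapered FFT every 100 ms, band-mean
power A(f,t) over the individually calibrated alpha band, and the
event-related desynchronization score

    ERD(t) = (R - A(t)) / R * 100

against the resting baseline band power R, clipped to [0, 100] for display
while the raw (unclipped) value is retained for analysis. Output at time t
uses only samples at or before t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .containers import Recording, TrialSchedule

__all__ = [
    "LaplacianSpec", "OnlineConfig", "SpectralEstimate", "ErdTimeSeries",
    "apply_laplacian", "causal_filter", "sliding_psd", "band_power",
    "erd_score", "run_online_session", "sham_replay",
]


@dataclass(frozen=True)
class LaplacianSpec:
    """Large Laplacian: center minus the mean of its six neighbours."""

    center: str = "C3"
    neighbors: tuple[str, ...] = ("FC5", "FC1", "C1", "CP1", "CP5", "C5")

    def __post_init__(self) -> None:
        if self.center in self.neighbors:
            raise ValueError("neighbors must exclude the center channel")
        if len(set(self.neighbors)) != len(self.neighbors):
            raise ValueError("duplicate neighbor channels")

    @property
    def weights(self) -> dict[str, float]:
        w = {self.center: 1.0}
        w.update({n: -1.0 / len(self.neighbors) for n in self.neighbors})
        return w


@dataclass
class OnlineConfig:
    """Parameters of the online scoring chain."""

    window_len: float = 1.0          # s, trailing FFT window
    update_step: float = 0.1         # s, score update interval
    bandpass: tuple[float, float] = (1.0, 70.0)
    bp_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    score_clip: tuple[float, float] = (0.0, 100.0)
    warmup: float = 1.0              # s of filter transient excluded

    def validate(self, srate: float) -> None:
        if self.bandpass[1] >= srate / 2:
            raise ValueError(
                f"band-pass upper cutoff {self.bandpass[1]} Hz >= Nyquist "
                f"({srate / 2} Hz)")
        if self.update_step > self.window_len:
            raise ValueError("update_step must not exceed window_len")
        n_win = self.window_len * srate
        if abs(n_win - round(n_win)) > 1e-9:
            raise ValueError("window_len * srate must be an integer")


@dataclass
class SpectralEstimate:
    """Time-frequency power density (µV²/Hz), one PSD per window.

    ``times[i]`` is the time of the *last* sample of window i (trailing,
    causal convention); ``values`` has shape (n_times, n_freqs).
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray


@dataclass
class ErdTimeSeries:
    """Feedback scores on the online update grid for one trial."""

    times: np.ndarray                # s, update grid
    scores: np.ndarray               # %, clipped to score_clip
    raw_erd: np.ndarray              # %, unclipped
    band: tuple[float, float]
    trial_index: int = 0

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def mean_raw_erd(self) -> float:
        return float(np.mean(self.raw_erd))


# ---------------------------------------------------------------------------

def apply_laplacian(rec: Recording, spec: LaplacianSpec) -> Recording:
    """Re-reference the center channel by the mean of its neighbours."""
    center = rec.channel(spec.center)
    neigh = np.stack([rec.channel(n) for n in spec.neighbors])
    out = center - neigh.mean(axis=0)
    meta = dict(rec.meta)
    meta["laplacian"] = {"center": spec.center, "neighbors": list(spec.neighbors)}
    return Recording(out[np.newaxis, :], rec.srate, [spec.center],
                     rec.start_time, meta)


def _design_sos(cfg: OnlineConfig, srate: float) -> np.ndarray:
    sos_bp = signal.butter(cfg.bp_order, cfg.bandpass, btype="bandpass",
                           fs=srate, output="sos")
    b, a = signal.iirnotch(cfg.notch_freq, cfg.notch_q, fs=srate)
    return np.vstack([sos_bp, signal.tf2sos(b, a)])


def causal_filter(rec: Recording, cfg: OnlineConfig) -> Recording:
    """Single-pass band-pass + notch; output at t uses only samples <= t."""
    cfg.validate(rec.srate)
    sos = _design_sos(cfg, rec.srate)
    data = signal.sosfilt(sos, rec.data, axis=1)
    return Recording(data, rec.srate, list(rec.labels), rec.start_time,
                     dict(rec.meta))


def sliding_psd(rec: Recording, cfg: OnlineConfig) -> SpectralEstimate:
    """Trailing-window Hann-tapered PSD every ``update_step`` seconds.

    With the default 1-s window at 1 kHz the frequency resolution is 1 Hz
    and adjacent windows overlap by 90 %.
    """
    cfg.validate(rec.srate)
    if rec.n_channels != 1:
        raise ValueError("sliding_psd expects a single-channel recording")
    x = rec.data[0]
    n_win = int(round(cfg.window_len * rec.srate))
    hop = int(round(cfg.update_step * rec.srate))
    if len(x) < n_win:
        raise ValueError(
            f"signal of {len(x)} samples shorter than the {n_win}-sample window")
    taper = signal.windows.hann(n_win, sym=False)
    frames = sliding_window_view(x, n_win)[::hop] * taper
    spec = np.fft.rfft(frames, axis=1)
    # one-sided density normalisation (DC/Nyquist bins not doubled)
    scale = 2.0 / (rec.srate * np.sum(taper ** 2))
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 0] /= 2.0
    if n_win % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n_win, d=1.0 / rec.srate)
    # time of the last sample in each window
    starts = np.arange(frames.shape[0]) * hop
    times = rec.start_time + (starts + n_win - 1) / rec.srate
    return SpectralEstimate(psd, times, freqs)


def band_power(est: SpectralEstimate, band: tuple[float, float]) -> np.ndarray:
    """Mean PSD across the integer-Hz bins of ``band`` (inclusive edges)."""
    lo, hi = band
    mask = (est.freqs >= lo - 1e-9) & (est.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} outside the PSD frequency range")
    return est.values[:, mask].mean(axis=1)


def erd_score(A: float | np.ndarray, R: float,
              clip: tuple[float, float] = (0.0, 100.0)
              ) -> tuple[np.ndarray, np.ndarray]:
    """ERD = (R - A) / R * 100; returns (clipped score, raw value)."""
    if R <= 0:
        raise ValueError(f"baseline band power must be positive, got {R}")
    raw = (R - np.asarray(A, dtype=float)) / R * 100.0
    return np.clip(raw, *clip), raw


def run_online_session(rec: Recording, calib, schedule: TrialSchedule,
                       cfg: OnlineConfig | None = None
                       ) -> list[ErdTimeSeries]:
    """Score a full session: Laplacian → causal filter → sliding PSD →
    band-mean A(t) → ERD against the calibration baseline R.

    Scores are emitted on the 100-ms grid only where the trailing window
    lies entirely within an imagery epoch (and past the filter warm-up).
    """
    cfg = cfg or OnlineConfig()
    cfg.validate(rec.srate)
    if calib.iaf_band[1] >= rec.srate / 2:
        raise ValueError("calibration band outside the PSD range")
    lap = apply_laplacian(rec, calib.laplacian)
    filt = causal_filter(lap, cfg)
    est = sliding_psd(filt, cfg)
    A = band_power(est, calib.iaf_band)
    R = calib.band_baseline(calib.iaf_band)
    scores, raw = erd_score(A, R, cfg.score_clip)

    out = []
    for i, trial in enumerate(schedule.trials):
        in_imagery = ((est.times - cfg.window_len >= trial.imagery_onset - 1e-9)
                      & (est.times <= trial.imagery_end + 1e-9)
                      & (est.times >= rec.start_time + cfg.warmup))
        out.append(ErdTimeSeries(est.times[in_imagery], scores[in_imagery],
                                 raw[in_imagery], tuple(calib.iaf_band), i))
    return out


def sham_replay(donor_scores: Sequence[ErdTimeSeries],
                recipient_schedule: TrialSchedule) -> list[ErdTimeSeries]:
    """Yoked-sham feedback: replay a donor's score sequence on the
    recipient's trial clock, ignoring the recipient's EEG entirely."""
    if len(donor_scores) == 0:
        raise ValueError("donor score sequence is empty")
    if len(donor_scores) < recipient_schedule.n_trials:
        raise ValueError(
            f"donor has {len(donor_scores)} trials, recipient needs "
            f"{recipient_schedule.n_trials}")
    out = []
    for i, trial in enumerate(recipient_schedule.trials):
        donor = donor_scores[i]
        times = trial.imagery_onset + (donor.times - donor.times[0]
                                       if len(donor.times) else donor.times)
        out.append(ErdTimeSeries(times, donor.scores.copy(),
                                 donor.raw_erd.copy(), donor.band, i))
    return out
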