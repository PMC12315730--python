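"""Synthetic EEG / EMG / MEP generators with recoverable ground truth.

Every generator draws from one seeded :class:`numpy.random.Generator` per
call and stores its ground-truth parameters in ``Recording.meta`` so that
downstream estimators (online ERD scoring, offline ERSP, EMG onset
detection, MEP peak-to-peak) have a known target.

Signal model
------------
EEG: each channel is independent 1/f-shaped Gaussian background noise plus
one shared common-mode 1/f component (so spatial filters have something to
cancel), 50 Hz line noise, and — on a "C3-like" target channel and, at a
configurable attenuation, its six neighbours — an amplitude-modulated mu
oscillator with an optional beta harmonic at twice the mu frequency. During
motor-imagery epochs the oscillator amplitude is scaled by
``sqrt(1 - erd_depth)`` so that mu-band *power* is attenuated by exactly
``erd_depth``; the attenuation ramps linearly across the 1-s ready epoch.

EMG: Gaussian baseline noise with a noise-carrier burst (rectified-envelope
morphology) starting at ``go_time + rt_true``.

MEP: damped sinusoid beginning ~20 ms after the stimulus, scaled so its
noise-free peak-to-peak equals the configured amplitude, plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import Recording, TrialSchedule

__all__ = [
    "EegGenConfig", "EmgGenConfig", "MepGenConfig", "CohortSpec",
    "DEFAULT_NEIGHBORS", "generate_eeg", "generate_emg_trial",
    "generate_emg_session", "generate_mep", "generate_mep_set",
    "generate_cohort", "pink_noise",
]

#: C3 and its six large-Laplacian neighbours in a 10-10-style montage.
DEFAULT_NEIGHBORS = ("FC5", "FC1", "C1", "CP1", "CP5", "C5")


# ---------------------------------------------------------------------------
# configs

@dataclass
class EegGenConfig:
    """Parameters of the synthetic EEG scene.

    ``mu_amp_rest`` (µV, sinusoid amplitude) and ``noise_amp`` (µV, total
    broadband sd) default to values for which the 1/f floor inside a 3-Hz
    scoring band contributes only a few percent of mu-band power after
    spatial filtering, so injected ERD depths are recoverable to a couple of
    percentage points.
    """

    target_channel: str = "C3"
    neighbor_channels: tuple[str, ...] = DEFAULT_NEIGHBORS
    mu_freq: float = 11.0
    mu_amp_rest: float = 25.0
    erd_depth: float = 0.5
    erd_depth_sd: float = 0.0        # per-trial depth jitter (free parameter)
    beta_coupling: float = 0.25      # beta harmonic amplitude / mu amplitude
    neighbor_mu_gain: float = 0.3
    noise_exponent: float = 1.0      # 1/f^exponent background
    noise_amp: float = 8.0           # broadband background sd per channel, µV
    common_mode_amp: float = 5.0     # shared across channels, µV sd
    line_noise_amp: float = 2.0      # 50 Hz, µV amplitude
    line_freq: float = 50.0
    srate: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.target_channel in self.neighbor_channels:
            raise ValueError("neighbor set must exclude the target channel")
        if len(set(self.neighbor_channels)) != len(self.neighbor_channels):
            raise ValueError("neighbor channels must be distinct")


@dataclass
class EmgGenConfig:
    rt_true: float = 0.150           # s after go cue
    burst_amp: float = 80.0          # µV, burst carrier sd
    baseline_sd: float = 10.0        # µV
    go_time: float = 1.0             # s
    burst_duration: float = 0.3      # s
    rise_time: float = 0.005         # s, linear onset ramp
    pre_cue_burst: bool = False
    srate: float = 10_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rt_true < 0:
            raise ValueError(f"rt_true must be non-negative, got {self.rt_true}")


@dataclass
class MepGenConfig:
    ptp_true: float = 1.0            # mV, noise-free peak-to-peak
    stim_time: float = 0.15          # s into the sweep
    latency: float = 0.020           # s from stimulus to response onset
    osc_freq: float = 80.0           # Hz of the damped oscillation
    damping: float = 60.0            # 1/s
    noise_sd: float = 0.0            # mV
    duration: float = 0.4            # s sweep length
    srate: float = 10_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ptp_true <= 0:
            raise ValueError(f"ptp_true must be positive, got {self.ptp_true}")
        if not 0 < self.stim_time < self.duration:
            raise ValueError("stim_time must fall inside the sweep")


@dataclass
class CohortSpec:
    """Two-group pre/post outcome model.

    Outcomes are drawn from ``grand mean + group-specific post shift +
    participant random intercept + residual``. ``shift_real`` / ``shift_sham``
    give the pre→post shift per outcome in outcome units.
    """

    n_per_group: int = 11
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"ersp_iaf": -30.0, "rt": 0.25, "sici_rt80": 55.0})
    shift_real: Mapping[str, float] = field(
        default_factory=lambda: {"ersp_iaf": -15.0, "rt": -0.010, "sici_rt80": 20.0})
    shift_sham: Mapping[str, float] = field(default_factory=dict)
    between_sd: Mapping[str, float] | float = field(
        default_factory=lambda: {"ersp_iaf": 8.0, "rt": 0.03, "sici_rt80": 10.0})
    within_sd: Mapping[str, float] | float = field(
        default_factory=lambda: {"ersp_iaf": 4.0, "rt": 0.008, "sici_rt80": 6.0})
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for sd in (self.between_sd, self.within_sd):
            vals = sd.values() if isinstance(sd, Mapping) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# noise primitives

def pink_noise(n: int, exponent: float, srate: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent power spectrum.

    The spectrum is flat below 1 Hz to keep the variance finite; with
    ``exponent=0`` this is plain white noise.
    """
    if n <= 1:
        return rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    shape = np.ones_like(freqs)
    if exponent != 0:
        f = np.maximum(freqs, 1.0)
        shape = f ** (-exponent / 2.0)
    spec = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs))) * shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# EEG

def _mu_envelope(times: np.ndarray, schedule: TrialSchedule, depths: np.ndarray
                 ) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1-depth) during imagery, linear
    amplitude ramp across the ready epoch."""
    env = np.ones_like(times)
    for trial, depth in zip(schedule.trials, depths):
        lo = np.sqrt(1.0 - depth)
        ramp = (times >= trial.ready_onset) & (times < trial.imagery_onset)
        frac = ((times[ramp] - trial.ready_onset)
                / (trial.imagery_onset - trial.ready_onset))
        env[ramp] = 1.0 + (lo - 1.0) * frac
        imag = (times >= trial.imagery_onset) & (times < trial.imagery_end)
        env[imag] = lo
    return env


def generate_eeg(cfg: EegGenConfig, schedule: TrialSchedule,
                 pad: float = 1.5) -> Recording:
    """Generate a multichannel EEG block following ``schedule``.

    The recording extends ``pad`` seconds beyond the last imagery offset so
    that offline epochs (imagery end + 1 s) always fit.
    """
    rng = np.random.default_rng(cfg.seed)
    duration = schedule.end_time + pad
    n = int(round(duration * cfg.srate))
    times = np.arange(n) / cfg.srate
    labels = [cfg.target_channel, *cfg.neighbor_channels]

    depths = np.clip(
        cfg.erd_depth + cfg.erd_depth_sd * rng.standard_normal(schedule.n_trials),
        0.0, 1.0)
    env = _mu_envelope(times, schedule, depths)

    # per-trial random phase; piecewise-constant phase offsets
    phase = np.full(n, rng.uniform(0, 2 * np.pi))
    phase_beta = np.full(n, rng.uniform(0, 2 * np.pi))
    for trial in schedule.trials:
        i0 = int(round(trial.rest_onset * cfg.srate))
        phase[i0:] = rng.uniform(0, 2 * np.pi)
        phase_beta[i0:] = rng.uniform(0, 2 * np.pi)
    mu = env * np.sin(2 * np.pi * cfg.mu_freq * times + phase)
    if cfg.beta_coupling > 0:
        mu = mu + cfg.beta_coupling * env * np.sin(
            2 * np.pi * 2.0 * cfg.mu_freq * times + phase_beta)

    common = cfg.common_mode_amp * pink_noise(n, cfg.noise_exponent, cfg.srate, rng)
    line = cfg.line_noise_amp * np.sin(
        2 * np.pi * cfg.line_freq * times + rng.uniform(0, 2 * np.pi))

    data = np.empty((len(labels), n))
    for i, label in enumerate(labels):
        gain = cfg.mu_amp_rest if i == 0 else cfg.mu_amp_rest * cfg.neighbor_mu_gain
        background = cfg.noise_amp * pink_noise(n, cfg.noise_exponent,
                                                cfg.srate, rng)
        data[i] = gain * mu + background + common + line

    meta = {
        "kind": "eeg", "seed": cfg.seed, "mu_freq": cfg.mu_freq,
        "erd_depth": cfg.erd_depth, "trial_depths": depths.tolist(),
        "target_channel": cfg.target_channel,
        "neighbor_channels": list(cfg.neighbor_channels),
        "mu_amp_rest": cfg.mu_amp_rest,
    }
    return Recording(data, cfg.srate, labels, 0.0, meta)


# ---------------------------------------------------------------------------
# EMG

def _burst(n_burst: int, rise_n: int, amp: float,
           rng: np.random.Generator) -> np.ndarray:
    env = np.ones(n_burst)
    if rise_n > 0:
        r = min(rise_n, n_burst)
        env[:r] = np.linspace(0.0, 1.0, r, endpoint=False) + 1.0 / r
    return amp * env * rng.standard_normal(n_burst)


def generate_emg_trial(cfg: EmgGenConfig, duration: float = 2.0) -> Recording:
    """One EMG trial: baseline noise plus a burst at ``go_time + rt_true``."""
    if cfg.go_time + cfg.rt_true >= duration:
        raise ValueError("go_time + rt_true must fall inside the trial")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration * cfg.srate))
    x = cfg.baseline_sd * rng.standard_normal(n)

    onset = cfg.go_time + cfg.rt_true
    i0 = int(round(onset * cfg.srate))
    nb = min(int(round(cfg.burst_duration * cfg.srate)), n - i0)
    rise_n = int(round(cfg.rise_time * cfg.srate))
    if cfg.burst_amp > 0 and nb > 0:
        x[i0:i0 + nb] += _burst(nb, rise_n, cfg.burst_amp, rng)

    pre_onset = None
    if cfg.pre_cue_burst:
        pre_onset = max(cfg.go_time - 0.5, 0.05)
        j0 = int(round(pre_onset * cfg.srate))
        nbp = min(int(round(0.2 * cfg.srate)), n - j0)
        x[j0:j0 + nbp] += _burst(nbp, rise_n, cfg.burst_amp, rng)

    meta = {"kind": "emg", "seed": cfg.seed, "go_time": cfg.go_time,
            "rt_true": cfg.rt_true, "onset_true": onset,
            "pre_cue_burst": cfg.pre_cue_burst, "pre_cue_onset": pre_onset}
    return Recording(x[np.newaxis, :], cfg.srate, ["EMG"], 0.0, meta)


def generate_emg_session(rt_trues: np.ndarray, cfg: EmgGenConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Recording, np.ndarray]:
    """A session of go-cue trials with inter-cue intervals of 6 ± 1 s.

    Returns the concatenated trace and the go-cue times.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_trials = len(rt_trues)
    intervals = rng.uniform(5.0, 7.0, size=n_trials)
    go_times = np.cumsum(intervals) - intervals[0] + 2.0  # first cue at 2 s
    duration = go_times[-1] + 2.0
    n = int(round(duration * cfg.srate))
    x = cfg.baseline_sd * rng.standard_normal(n)
    rise_n = int(round(cfg.rise_time * cfg.srate))
    for go, rt in zip(go_times, rt_trues):
        i0 = int(round((go + rt) * cfg.srate))
        nb = min(int(round(cfg.burst_duration * cfg.srate)), n - i0)
        if nb > 0 and cfg.burst_amp > 0:
            x[i0:i0 + nb] += _burst(nb, rise_n, cfg.burst_amp, rng)
    meta = {"kind": "emg_session", "go_times": go_times.tolist(),
            "rt_trues": np.asarray(rt_trues).tolist()}
    return Recording(x[np.newaxis, :], cfg.srate, ["EMG"], 0.0, meta), go_times


# ---------------------------------------------------------------------------
# MEP

def mep_waveform(cfg: MepGenConfig) -> np.ndarray:
    """Noise-free MEP sweep (mV) whose peak-to-peak equals ``ptp_true``."""
    n = int(round(cfg.duration * cfg.srate))
    t = np.arange(n) / cfg.srate
    tau = t - (cfg.stim_time + cfg.latency)
    w = np.where(tau >= 0,
                 np.sin(2 * np.pi * cfg.osc_freq * tau) * np.exp(-cfg.damping * np.maximum(tau, 0)),
                 0.0)
    span = w.max() - w.min()
    return w * (cfg.ptp_true / span)


def generate_mep(cfg: MepGenConfig) -> Recording:
    """One MEP sweep in microvolts (config amplitudes are millivolts)."""
    rng = np.random.default_rng(cfg.seed)
    w = mep_waveform(cfg)
    if cfg.noise_sd > 0:
        w = w + cfg.noise_sd * rng.standard_normal(len(w))
    meta = {"kind": "mep", "seed": cfg.seed, "ptp_true": cfg.ptp_true,
            "stim_time": cfg.stim_time, "latency": cfg.latency}
    return Recording(1000.0 * w[np.newaxis, :], cfg.srate, ["EMG"], 0.0, meta)


def generate_mep_set(ptp_by_cell: Mapping[tuple[str, str], float],
                     n_by_cell: Mapping[tuple[str, str], int] | int = 7,
                     noise_sd: float = 0.0, seed: int | None = None,
                     **cfg_kwargs) -> list[tuple[str, str, Recording]]:
    """Sweeps for each (protocol, condition) cell.

    ``ptp_by_cell`` maps e.g. ``("single", "rest")`` to a true peak-to-peak
    in mV. Returns a list of (protocol, condition, sweep) tuples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (protocol, condition), ptp in ptp_by_cell.items():
        n = n_by_cell if isinstance(n_by_cell, int) else n_by_cell[(protocol, condition)]
        for _ in range(n):
            cfg = MepGenConfig(ptp_true=ptp, noise_sd=noise_sd,
                               seed=int(rng.integers(2 ** 31)), **cfg_kwargs)
            out.append((protocol, condition, generate_mep(cfg)))
    return out


# ---------------------------------------------------------------------------
# cohort (outcome level)

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Pre/post outcome table for a real and a sham group.

    One row per participant × time with columns ``participant, group, time``
    plus one column per outcome. Ground-truth shifts are stored in
    ``df.attrs["ground_truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    outcomes = list(spec.baseline)

    def sd_of(mapping, o):
        return mapping[o] if isinstance(mapping, Mapping) else mapping

    rows = []
    pid = 0
    for group, shifts in (("real", spec.shift_real), ("sham", spec.shift_sham)):
        for _ in range(spec.n_per_group):
            pid += 1
            intercepts = {o: rng.normal(0.0, sd_of(spec.between_sd, o))
                          for o in outcomes}
            for time in ("pre", "post"):
                row = {"participant": f"P{pid:02d}", "group": group, "time": time}
                for o in outcomes:
                    shift = shifts.get(o, 0.0) if time == "post" else 0.0
                    row[o] = (spec.baseline[o] + shift + intercepts[o]
                              + rng.normal(0.0, sd_of(spec.within_sd, o)))
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "shift_real": dict(spec.shift_real), "shift_sham": dict(spec.shift_sham),
        "seed": spec.seed}
    return df
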