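"""Per-participant spectral calibration from a no-feedback evaluation block.

Derives the resting baseline spectrum R(f) (per-frequency median over all
resting windows), the individual alpha frequency band (the 3-Hz window in
8–13 Hz with the most pronounced mean ERD) and the individual beta band
(twice the IAF band center ± 2 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import Recording, TrialSchedule
from .online import (LaplacianSpec, OnlineConfig, SpectralEstimate,
                     apply_laplacian, causal_filter, sliding_psd)

__all__ = ["CalibrationResult", "compute_baseline", "select_iaf",
           "derive_ibf", "calibrate", "IAF_RANGE", "IAF_WIDTH"]

IAF_RANGE = (8.0, 13.0)
IAF_WIDTH = 3.0


@dataclass
class CalibrationResult:
    """Baseline spectrum and individual scoring bands."""

    freqs: np.ndarray                 # Hz, 1-Hz grid
    R: np.ndarray                     # µV²/Hz, median rest PSD per bin
    iaf_band: tuple[float, float]     # [lo, hi], hi - lo = 3
    iaf_median: float                 # band center frequency
    ibf_band: tuple[float, float]
    laplacian: LaplacianSpec
    erd_by_freq: dict[int, float] | None = None

    def band_baseline(self, band: tuple[float, float]) -> float:
        """Band-mean of R over integer bins in [lo, hi] inclusive."""
        mask = (self.freqs >= band[0] - 1e-9) & (self.freqs <= band[1] + 1e-9)
        if not mask.any():
            raise ValueError(f"band {band} outside calibration spectrum")
        r = float(self.R[mask].mean())
        if r <= 0:
            raise ValueError("baseline band power must be positive")
        return r

    def to_json(self, path: str | Path) -> None:
        payload = {
            "freqs": self.freqs.tolist(), "R": self.R.tolist(),
            "iaf_band": list(self.iaf_band), "iaf_median": self.iaf_median,
            "ibf_band": list(self.ibf_band),
            "laplacian": {"center": self.laplacian.center,
                          "neighbors": list(self.laplacian.neighbors)},
            "erd_by_freq": ({str(k): v for k, v in self.erd_by_freq.items()}
                            if self.erd_by_freq else None),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["freqs"]), np.asarray(d["R"]),
                   tuple(d["iaf_band"]), d["iaf_median"], tuple(d["ibf_band"]),
                   LaplacianSpec(d["laplacian"]["center"],
                                 tuple(d["laplacian"]["neighbors"])),
                   {int(k): v for k, v in d["erd_by_freq"].items()}
                   if d.get("erd_by_freq") else None)


def compute_baseline(rest_windows: np.ndarray | SpectralEstimate) -> np.ndarray:
    """Per-frequency median PSD across resting windows (rows)."""
    values = (rest_windows.values if isinstance(rest_windows, SpectralEstimate)
              else np.atleast_2d(np.asarray(rest_windows, dtype=float)))
    if values.size == 0:
        raise ValueError("need at least one resting window")
    return np.median(values, axis=0)


def candidate_bands(lo: float = IAF_RANGE[0], hi: float = IAF_RANGE[1],
                    width: float = IAF_WIDTH) -> list[tuple[float, float]]:
    """Integer-edged candidate windows of the given width inside [lo, hi]."""
    starts = np.arange(lo, hi - width + 1e-9)
    return [(float(s), float(s + width)) for s in starts]


def select_iaf(erd_by_freq: dict[int, float] | dict[float, float]
               ) -> tuple[tuple[float, float], float]:
    """Pick the 3-Hz window in 8–13 Hz with maximal mean ERD.

    ``erd_by_freq`` maps integer frequencies 8..13 to mean ERD (%). Ties go
    to the lowest-frequency band. Returns (band, band center).
    """
    erd = {int(k): float(v) for k, v in erd_by_freq.items()}
    needed = set(range(int(IAF_RANGE[0]), int(IAF_RANGE[1]) + 1))
    missing = needed - set(erd)
    if missing:
        raise ValueError(f"missing ERD bins: {sorted(missing)}")
    best_band, best_mean = None, -np.inf
    for band in candidate_bands():
        bins = [f for f in erd if band[0] <= f <= band[1]]
        mean = float(np.mean([erd[f] for f in bins]))
        if mean > best_mean + 1e-12:   # strict improvement: lowest band wins ties
            best_band, best_mean = band, mean
    return best_band, (best_band[0] + best_band[1]) / 2.0


def derive_ibf(iaf_median: float) -> tuple[float, float]:
    """Individual beta band: twice the IAF center ± 2 Hz."""
    if not IAF_RANGE[0] <= iaf_median <= IAF_RANGE[1]:
        raise ValueError(f"IAF center {iaf_median} outside {IAF_RANGE}")
    return (2.0 * iaf_median - 2.0, 2.0 * iaf_median + 2.0)


def calibrate(rec: Recording, schedule: TrialSchedule,
              laplacian: LaplacianSpec | None = None,
              cfg: OnlineConfig | None = None) -> CalibrationResult:
    """Full calibration from an evaluation-block recording.

    Runs the online chain (Laplacian → causal filter → sliding PSD), takes
    the per-frequency median over all resting windows as R(f), computes the
    mean ERD per integer bin over all imagery windows, and selects the IAF
    and IBF bands. Deterministic: rerunning on the same block reproduces
    identical results.
    """
    laplacian = laplacian or LaplacianSpec()
    cfg = cfg or OnlineConfig()
    est = sliding_psd(causal_filter(apply_laplacian(rec, laplacian), cfg), cfg)

    t0 = rec.start_time + cfg.warmup
    rest = np.zeros(len(est.times), dtype=bool)
    imagery = np.zeros(len(est.times), dtype=bool)
    for tr in schedule.trials:
        rest |= ((est.times - cfg.window_len >= tr.rest_onset - 1e-9)
                 & (est.times <= tr.ready_onset + 1e-9))
        imagery |= ((est.times - cfg.window_len >= tr.imagery_onset - 1e-9)
                    & (est.times <= tr.imagery_end + 1e-9))
    rest &= est.times >= t0
    imagery &= est.times >= t0
    if not rest.any() or not imagery.any():
        raise ValueError("schedule yields no usable rest or imagery windows")

    R = compute_baseline(est.values[rest])
    erd_by_freq: dict[int, float] = {}
    for f in range(int(IAF_RANGE[0]), int(IAF_RANGE[1]) + 1):
        bin_idx = int(np.argmin(np.abs(est.freqs - f)))
        r = R[bin_idx]
        A = est.values[imagery, bin_idx]
        erd_by_freq[f] = float(np.mean((r - A) / r * 100.0))

    iaf_band, iaf_median = select_iaf(erd_by_freq)
    return CalibrationResult(est.freqs, R, iaf_band, iaf_median,
                             derive_ibf(iaf_median), laplacian, erd_by_freq)
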