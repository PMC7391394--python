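"""Heart-rate-variability analysis of interbeat-interval (RR) series.

Respiratory sinus arrhythmia couples breathing to heart rate: inhalation
transiently inhibits vagal tone and speeds the heart, exhalation slows
it.  Slow breathing near the ~0.1 Hz resonance frequency therefore
shifts the RR spectrum's respiratory peak from the high-frequency band
(0.15–0.4 Hz) into the low-frequency band (0.04–0.15 Hz) and increases
vagally mediated variability.

This module provides the standard quantification chain: physiologically
implausible intervals (outside 350–1800 ms) are replaced by linear
interpolation, RMSSD is computed on the cleaned series, and VLF/LF/HF
band powers are integrated from a Welch PSD of the tachogram resampled
to a uniform 4 Hz grid.  Band powers are in ms² (integral of the
density over the band), RMSSD in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.signal import welch

__all__ = [
    "RRSeries",
    "HRVConfig",
    "HRVSummary",
    "clean_rr",
    "rmssd",
    "band_powers",
    "summarize_hrv",
]


@dataclass(frozen=True)
class RRSeries:
    """A sequence of interbeat intervals in milliseconds.

    Beat times are implicit: the k-th beat occurs at the cumulative sum
    of the first k intervals.
    """

    intervals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("non-finite interbeat interval")

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def beat_times_s(self) -> np.ndarray:
        """Beat times in seconds from the first interval onward."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)


class HRVConfig(BaseModel):
    """Cleaning bounds, resampling rate, frequency bands, Welch settings."""

    rr_low_bound: float = Field(default=350.0, gt=0.0)
    rr_high_bound: float = Field(default=1800.0, gt=0.0)
    resample_rate: float = Field(default=4.0, gt=0.0)
    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)
    welch_segment: int = Field(default=256, ge=8)
    welch_overlap: float = Field(default=0.5, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "HRVConfig":
        if self.rr_low_bound >= self.rr_high_bound:
            raise ValueError("rr_low_bound must be < rr_high_bound")
        bands = [self.vlf, self.lf, self.hf]
        for lo, hi in bands:
            if not 0 <= lo < hi:
                raise ValueError("each band must satisfy 0 <= low < high")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if lo < hi:
                raise ValueError("bands must be ordered and non-overlapping")
        return self


@dataclass(frozen=True)
class HRVSummary:
    """RMSSD (ms), band-integrated powers (ms²) and the cleaning count."""

    rmssd: float
    power_vlf: float
    power_lf: float
    power_hf: float
    n_outliers_replaced: int

    def to_dict(self) -> dict:
        return {
            "rmssd": self.rmssd,
            "power_vlf": self.power_vlf,
            "power_lf": self.power_lf,
            "power_hf": self.power_hf,
            "n_outliers_replaced": self.n_outliers_replaced,
        }


def _as_series(rr: RRSeries | Sequence[float]) -> RRSeries:
    return rr if isinstance(rr, RRSeries) else RRSeries(np.asarray(rr, dtype=float))


def clean_rr(rr: RRSeries | Sequence[float], cfg: HRVConfig | None = None) -> tuple[RRSeries, int]:
    """Replace out-of-bounds intervals by linear interpolation over index.

    Intervals above ``rr_high_bound`` or below ``rr_low_bound`` are
    treated as outliers (missed/spurious beats) and replaced by the
    linear interpolant between the nearest in-bounds neighbours;
    leading/trailing outliers take the nearest in-bounds value.
    Idempotent: interpolated values always lie between in-bounds
    neighbours, hence in bounds.
    """
    cfg = cfg or HRVConfig()
    rr = _as_series(rr)
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    x = rr.intervals
    good = (x >= cfg.rr_low_bound) & (x <= cfg.rr_high_bound)
    n_bad = int(np.sum(~good))
    if n_bad == 0:
        return RRSeries(x.copy()), 0
    if not np.any(good):
        raise ValueError("no in-bounds intervals to interpolate from")
    idx = np.arange(x.shape[0])
    cleaned = x.copy()
    cleaned[~good] = np.interp(idx[~good], idx[good], x[good])
    return RRSeries(cleaned), n_bad


def rmssd(rr: RRSeries | Sequence[float]) -> float:
    """Root mean square of successive interbeat-interval differences (ms)."""
    rr = _as_series(rr)
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.diff(rr.intervals)
    return float(np.sqrt(np.mean(diffs**2)))


def band_powers(
    rr: RRSeries | Sequence[float], cfg: HRVConfig | None = None
) -> tuple[float, float, float]:
    """VLF, LF and HF power (ms²) of the resampled tachogram.

    The interval series is placed at its beat times, linearly
    interpolated onto a uniform ``resample_rate`` grid, mean-removed and
    passed through Welch's method; each band power is the trapezoidal
    integral of the density over the band.  A series shorter than one
    Welch segment shrinks the segment to the series length; fewer than
    two grid points is an error.
    """
    cfg = cfg or HRVConfig()
    rr = _as_series(rr)
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    t = rr.beat_times_s
    grid = np.arange(t[0], t[-1], 1.0 / cfg.resample_rate)
    if grid.shape[0] < 8:  # below the smallest admissible Welch segment
        raise ValueError("series too short for spectral analysis")
    tach = np.interp(grid, t, rr.intervals)
    nperseg = min(cfg.welch_segment, grid.shape[0])
    freqs, psd = welch(
        tach,
        fs=cfg.resample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * cfg.welch_overlap),
        detrend="constant",
    )

    def integrate(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if np.sum(mask) < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    return integrate(*cfg.vlf), integrate(*cfg.lf), integrate(*cfg.hf)


def summarize_hrv(rr: RRSeries | Sequence[float], cfg: HRVConfig | None = None) -> HRVSummary:
    """Clean, then compute RMSSD and band powers in one pass."""
    cfg = cfg or HRVConfig()
    cleaned, n_replaced = clean_rr(rr, cfg)
    vlf, lf, hf = band_powers(cleaned, cfg)
    return HRVSummary(
        rmssd=rmssd(cleaned),
        power_vlf=vlf,
        power_lf=lf,
        power_hf=hf,
        n_outliers_replaced=n_replaced,
    )
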