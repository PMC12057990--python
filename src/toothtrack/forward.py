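"""Forward model: predict an intra-tooth Sr profile from a movement
track and an isoscape.

A GPS track is annotated with the isoscape ratio at each fix
(nearest-cell, half-open convention).  Fixes are treated as residence
samples weighted by inter-fix duration: the annotated series holds each
fix's ratio until the next fix, and the tooth recorder then applies the
same rectangular maturation kernel as the simulator
(:mod:`toothtrack.recording`), noise-free.  Comparing the prediction
with a measured profile quantifies how well the isoscape plus the
recorded movements explain the enamel record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Isoscape
from .profiles import IsotopeProfile
from .recording import ToothTiming, sample_tooth

log = logging.getLogger(__name__)


@dataclass
class Track:
    """A movement track: times (days), planar positions (m), optional
    elevations (m)."""

    t_days: np.ndarray
    x: np.ndarray
    y: np.ndarray
    elevation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_days = np.asarray(self.t_days, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t_days.shape == self.x.shape == self.y.shape):
            raise ValueError("track arrays must share a length")
        if np.any(np.diff(self.t_days) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)
            if self.elevation.shape != self.t_days.shape:
                raise ValueError("elevation length mismatch")

    @classmethod
    def from_csv(cls, path) -> "Track":
        df = pd.read_csv(path)
        elev = df["elevation"].to_numpy() if "elevation" in df else None
        return cls(df["timestamp"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), elev)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"timestamp": self.t_days, "x": self.x, "y": self.y})
        if self.elevation is not None:
            df["elevation"] = self.elevation
        df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class AnnotatedTrack:
    """Per-fix isoscape ratios plus bookkeeping on exclusions and gaps."""

    t_days: np.ndarray
    ratio: np.ndarray
    n_excluded: int = 0
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def to_series(self, dt_days: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Residence-weighted continuous series: each fix's ratio is held
        until the next fix (previous-fix hold), sampled every
        ``dt_days``.  This weights fixes by inter-fix duration rather
        than by count."""
        if self.t_days.size == 0:
            raise ValueError("empty annotated track")
        t = np.arange(self.t_days[0], self.t_days[-1] + dt_days / 2, dt_days)
        idx = np.searchsorted(self.t_days, t, side="right") - 1
        return t, self.ratio[np.clip(idx, 0, self.ratio.size - 1)]


def annotate_track(
    track: Track, isoscape: Isoscape, gap_threshold_days: float = 14.0
) -> AnnotatedTrack:
    """Extract the isoscape ratio at each GPS fix.

    Fixes outside the isoscape extent are excluded (count reported);
    inter-fix intervals longer than ``gap_threshold_days`` are flagged
    as gaps.
    """
    inside = isoscape.mean.contains(track.x, track.y)
    n_excluded = int((~inside).sum())
    if n_excluded:
        log.warning("annotate_track: %d fix(es) outside the isoscape extent excluded",
                    n_excluded)
    t = track.t_days[inside]
    ratio = isoscape.mean.lookup(track.x[inside], track.y[inside])
    ratio = np.atleast_1d(ratio)
    gaps = [
        (float(t[i]), float(t[i + 1]))
        for i in np.flatnonzero(np.diff(t) > gap_threshold_days)
    ]
    return AnnotatedTrack(t_days=t, ratio=ratio, n_excluded=n_excluded, gaps=gaps)


def predict_profile(
    series_time: np.ndarray,
    series_values: np.ndarray,
    timing: ToothTiming,
    maturation_window_days: float = 180.0,
    n_samples: int = 60,
    tooth_id: str = "predicted",
) -> IsotopeProfile:
    """Predict the noise-free recorded profile from an environmental
    series (e.g. an annotated track resampled to days).

    Shares the recording kernel with the simulator; a coverage gap
    inside the formation window raises with the missing interval.
    """
    t0 = timing.start_day
    t1 = timing.end_day + maturation_window_days
    lo, hi = float(np.min(series_time)), float(np.max(series_time))
    if t0 < lo or t1 > hi:
        raise ValueError(
            "track series does not cover the tooth formation window: "
            f"need [{t0:.1f}, {t1:.1f}] d, have [{lo:.1f}, {hi:.1f}] d"
        )
    distances, values = sample_tooth(
        series_time, series_values, timing, maturation_window_days, n_samples
    )
    return IsotopeProfile(
        tooth_id=tooth_id,
        isotope="Sr",
        distance_mm=distances,
        value=values,
        metadata={"tooth_label": timing.tooth_label,
                  "maturation_window_days": maturation_window_days},
    )


def compare_profiles(
    predicted: IsotopeProfile, measured: IsotopeProfile, n_grid: int = 200
) -> dict:
    """RMSE, mean bias (measured - predicted) and Spearman rank
    correlation after resampling both profiles onto a common distance
    grid (linear interpolation over the overlap)."""
    lo = max(predicted.distance_mm.min(), measured.distance_mm.min())
    hi = min(predicted.distance_mm.max(), measured.distance_mm.max())
    if hi <= lo:
        raise ValueError("profiles have non-overlapping distance ranges")
    grid = np.linspace(lo, hi, n_grid)

    def resample(p: IsotopeProfile) -> np.ndarray:
        d, v = p.distance_mm, p.value
        if d[0] > d[-1]:
            d, v = d[::-1], v[::-1]
        return np.interp(grid, d, v)

    pv = resample(predicted)
    mv = resample(measured)
    diff = mv - pv
    rho = stats.spearmanr(pv, mv).statistic if np.ptp(pv) > 0 and np.ptp(mv) > 0 else np.nan
    return {
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "bias": float(np.mean(diff)),
        "spearman": float(rho),
        "overlap_mm": (float(lo), float(hi)),
    }
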