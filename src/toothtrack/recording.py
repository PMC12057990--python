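"""The enamel recording kernel shared by the simulator and the forward model.

Hypsodont enamel does not snapshot the environment: each crown position
mineralizes over an extended maturation window, so the recorded value is a
moving average of the environmental input.  We model this with a
rectangular kernel: the value recorded at crown position with nominal age
``t`` is the mean of the environmental series over ``[t, t + window]``.

Crown geometry follows a linear distance-time mapping: the crown apex
(distance = crown length from the enamel-root junction, ERJ) forms at the
start age, the ERJ at the end age, and age varies linearly in between.
Distances are reported in mm from the ERJ, so age *decreases* with
increasing distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass
class ToothTiming:
    """Mineralization timing and crown geometry for one molar.

    Ages are in months from birth with 1-sigma uncertainties; the defaults
    are published modern-horse values (M1 0.5+-1 to 23+-3, M2 7+-1.5 to
    37+-3, M3 21+-3 to 55+-2 months), which integrate environmental input
    over about 1.9, 2.5 and 2.8 years respectively.
    """

    tooth_label: str
    start_age_months: float
    start_sd_months: float
    end_age_months: float
    end_sd_months: float
    crown_length_mm: float

    def __post_init__(self) -> None:
        if self.end_age_months <= self.start_age_months:
            raise ValueError("end age must exceed start age")
        if self.crown_length_mm <= 0:
            raise ValueError("crown length must be positive")

    @property
    def start_day(self) -> float:
        return self.start_age_months * DAYS_PER_MONTH

    @property
    def end_day(self) -> float:
        return self.end_age_months * DAYS_PER_MONTH

    @property
    def integration_years(self) -> float:
        """Total span of environmental input integrated by the crown."""
        return (self.end_age_months - self.start_age_months) / 12.0

    def age_at_distance(self, distance_mm) -> np.ndarray:
        """Formation age (days) at a distance (mm) from the ERJ."""
        d = np.asarray(distance_mm, dtype=float)
        frac = d / self.crown_length_mm
        return self.end_day - frac * (self.end_day - self.start_day)


#: Default timings for the three mandibular/maxillary molars.  Crown
#: lengths are typical unworn values for domestic horses (mm).
TOOTH_TIMINGS: dict[str, ToothTiming] = {
    "M1": ToothTiming("M1", 0.5, 1.0, 23.0, 3.0, crown_length_mm=60.0),
    "M2": ToothTiming("M2", 7.0, 1.5, 37.0, 3.0, crown_length_mm=70.0),
    "M3": ToothTiming("M3", 21.0, 3.0, 55.0, 2.0, crown_length_mm=80.0),
}


def window_mean(time: np.ndarray, values: np.ndarray, starts: np.ndarray,
                window_days: float) -> np.ndarray:
    """Mean of a sampled series over ``[start, start + window]`` per start.

    The series is treated as piecewise linear between samples (trapezoidal
    cumulative integral), so a daily-sampled step input yields an exact
    linear ramp response of extent ``window_days``.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    starts = np.asarray(starts, dtype=float)
    if window_days < 0:
        raise ValueError("window must be non-negative")
    if window_days == 0:
        return np.interp(starts, time, values)
    lo, hi = time[0], time[-1]
    if np.any(starts < lo - 1e-9) or np.any(starts + window_days > hi + 1e-9):
        raise ValueError(
            "environmental series does not cover the recording windows: "
            f"need [{starts.min():.1f}, {(starts + window_days).max():.1f}] d, "
            f"have [{lo:.1f}, {hi:.1f}] d"
        )
    cum = np.concatenate([[0.0], cumulative_trapezoid(values, time)])
    c0 = np.interp(starts, time, cum)
    c1 = np.interp(starts + window_days, time, cum)
    return (c1 - c0) / window_days


def sample_tooth(time: np.ndarray, values: np.ndarray, timing: ToothTiming,
                 maturation_window_days: float, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample a recorded profile along the crown.

    Returns ``(distance_mm_from_ERJ, recorded_value)`` with distances
    strictly increasing from just above the ERJ to the crown apex.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples along the crown")
    distances = np.linspace(0.0, timing.crown_length_mm, n_samples)
    ages = timing.age_at_distance(distances)
    recorded = window_mean(time, values, ages, maturation_window_days)
    return distances, recorded
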