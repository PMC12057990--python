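"""Synthetic study worlds with known ground truth.

Everything downstream of raw data ingestion can be exercised on data from
this module: a patchy 87Sr/86Sr isoscape (smooth background plus discrete
lithological patches, with a per-cell SD layer), camp-to-camp seasonal
movement schedules, environmental time series (isoscape Sr at the
occupied camp, a sinusoidal annual d18O signal, elevation-driven d13C),
tooth-recorded profiles with mineralization averaging and analytical
noise, and radiocarbon dates drawn from a known occupation phase.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import Grid, Isoscape
from .profiles import IsotopeProfile
from .recording import ToothTiming, sample_tooth
from .season import ElevationModel

__all__ = [
    "MovementSchedule",
    "EnvironmentSeries",
    "make_isoscape",
    "make_seasonal_schedule",
    "simulate_environment",
    "record_tooth",
    "make_radiocarbon_dataset",
    "synthetic_curve",
]


@dataclass
class MovementSchedule:
    """Timestamped sequence of camp residencies driving the recorder.

    ``camps`` is a list of ``(x, y, elevation_m)``; ``occupancy`` a list
    of ``(camp_index, start_day, end_day)`` intervals that must be
    contiguous, non-overlapping and cover the simulated period.
    """

    camps: list[tuple[float, float, float]]
    occupancy: list[tuple[int, float, float]]
    year_length: float = 365.0

    def __post_init__(self) -> None:
        if not self.camps or not self.occupancy:
            raise ValueError("schedule needs at least one camp and one occupancy interval")
        prev_end = None
        for idx, start, end in self.occupancy:
            if not 0 <= idx < len(self.camps):
                raise ValueError(f"camp index {idx} out of range")
            if end <= start:
                raise ValueError("occupancy interval must have positive duration")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("occupancy intervals must be contiguous and non-overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[float, float]:
        return self.occupancy[0][1], self.occupancy[-1][2]

    def camp_at(self, day) -> np.ndarray:
        """Index of the occupied camp at each day (end day belongs to the
        following interval, last end inclusive)."""
        day = np.atleast_1d(np.asarray(day, dtype=float))
        starts = np.array([s for _, s, _ in self.occupancy])
        first, last = self.span
        if np.any(day < first) or np.any(day > last):
            raise ValueError("day outside scheduled period")
        pos = np.searchsorted(starts, day, side="right") - 1
        idx = np.array([self.occupancy[p][0] for p in pos])
        return idx

    def n_relocations(self) -> int:
        """Number of camp changes actually scheduled."""
        seq = [idx for idx, _, _ in self.occupancy]
        return int(np.sum(np.diff(seq) != 0))

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "year_length": self.year_length,
            "camps": [list(c) for c in self.camps],
            "occupancy": [[int(i), float(s), float(e)] for i, s, e in self.occupancy],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "MovementSchedule":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            camps=[tuple(c) for c in data["camps"]],
            occupancy=[tuple(o) for o in data["occupancy"]],
            year_length=float(data.get("year_length", 365.0)),
        )


@dataclass
class EnvironmentSeries:
    """Daily environmental input experienced by one animal."""

    time: np.ndarray
    sr_ratio: np.ndarray
    d18O: np.ndarray
    d13C_enamel: np.ndarray
    elevation: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.time, self.sr_ratio, self.d18O, self.d13C_enamel, self.elevation]
        for i, arr in enumerate(arrays):
            arrays[i] = np.asarray(arr, dtype=float)
        self.time, self.sr_ratio, self.d18O, self.d13C_enamel, self.elevation = arrays
        n = self.time.size
        if any(a.size != n for a in arrays[1:]):
            raise ValueError("all series must share a length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def series(self, isotope: str) -> np.ndarray:
        return {"Sr": self.sr_ratio, "d18O": self.d18O, "d13C": self.d13C_enamel}[isotope]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.time,
                "sr_ratio": self.sr_ratio,
                "d18O": self.d18O,
                "d13C_enamel": self.d13C_enamel,
                "elevation_m": self.elevation,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def make_isoscape(
    shape: tuple[int, int] = (64, 64),
    n_patches: int = 5,
    background_smoothness: float = 6.0,
    ratio_range: tuple[float, float] = (0.702, 0.725),
    sd_level: float = 0.001,
    seed: int = 0,
    cell_size: float = 2000.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Isoscape:
    """Generate a patchy synthetic 87Sr/86Sr isoscape.

    The mean surface is a smooth background (Gaussian-filtered white
    noise, correlation length ``background_smoothness`` cells) spanning
    the middle of ``ratio_range``, overlaid with ``n_patches`` connected
    elliptical patches of distinct ratios drawn across the full range -
    emulating discrete lithological units against a regional gradient.
    The SD layer is ``sd_level`` modulated smoothly by +-50%.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError("grid must be at least 8x8")
    if n_patches < 0:
        raise ValueError("n_patches must be non-negative")
    if sd_level <= 0:
        raise ValueError("sd_level must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = ratio_range
    if hi < lo:
        raise ValueError("ratio_range must be (low, high)")
    span = hi - lo

    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=background_smoothness)
    rng_span = smooth.max() - smooth.min()
    if rng_span > 0 and span > 0:
        # background occupies the central 60% of the ratio range
        bg_lo, bg_hi = lo + 0.2 * span, hi - 0.2 * span
        mean = bg_lo + (smooth - smooth.min()) / rng_span * (bg_hi - bg_lo)
    else:
        mean = np.full(shape, (lo + hi) / 2.0)

    rows, cols = np.indices(shape)
    for _ in range(n_patches):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ry = rng.uniform(0.05, 0.25) * shape[0]
        rx = rng.uniform(0.05, 0.25) * shape[1]
        theta = rng.uniform(0, np.pi)
        dy, dx = rows - cy, cols - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        mean[mask] = rng.uniform(lo, hi)
    mean = np.clip(mean, lo, hi)

    sd_mod = gaussian_filter(rng.standard_normal(shape), sigma=background_smoothness)
    mod_span = sd_mod.max() - sd_mod.min()
    if mod_span > 0:
        sd = sd_level * (0.5 + (sd_mod - sd_mod.min()) / mod_span)
    else:
        sd = np.full(shape, sd_level)

    meta = {"seed": seed, "n_patches": n_patches, "ratio_range": ratio_range}
    return Isoscape(
        Grid(mean, cell_size, origin), Grid(sd, cell_size, origin), metadata=meta
    )


def make_seasonal_schedule(
    camps: list[tuple[float, float, float]],
    moves_per_year: int = 4,
    n_years: float = 5.0,
    year_length: float = 365.0,
    start_day: float = 0.0,
) -> MovementSchedule:
    """Cyclic seasonal rounds: visit camps in order, ``moves_per_year``
    camp changes per year with equal residence times."""
    if moves_per_year < 1:
        raise ValueError("need at least one move per year")
    stay = year_length / moves_per_year
    n_stays = int(np.ceil(n_years * moves_per_year))
    occupancy = []
    t = start_day
    for k in range(n_stays):
        occupancy.append((k % len(camps), t, t + stay))
        t += stay
    return MovementSchedule(camps=camps, occupancy=occupancy, year_length=year_length)


def simulate_environment(
    schedule: MovementSchedule,
    isoscape: Isoscape,
    d18O_params: dict | None = None,
    elevation_model: ElevationModel | None = None,
    dt_days: float = 1.0,
) -> EnvironmentSeries:
    """Environmental series experienced under a movement schedule.

    Per day: Sr ratio is the isoscape mean at the occupied camp; d18O is
    ``mean + amplitude * sin(2*pi*(t - phase_day)/year_length)``; enamel
    d13C follows the elevation model's forward chain (diet d13C from camp
    elevation, plus the diet-to-enamel fractionation) before any
    analytical noise, which is added only at tooth recording.
    """
    p = {"mean": -12.8, "amplitude": 2.45, "phase_day": 120.0}
    if d18O_params:
        p.update(d18O_params)
    em = elevation_model or ElevationModel()
    for i, (x, y, _elev) in enumerate(schedule.camps):
        if not np.all(isoscape.mean.contains(x, y)):
            raise ValueError(f"camp {i} at ({x:g}, {y:g}) lies outside the isoscape extent")
    t0, t1 = schedule.span
    time = np.arange(t0, t1 + dt_days / 2, dt_days)
    camp_idx = schedule.camp_at(time)
    xs = np.array([schedule.camps[i][0] for i in camp_idx])
    ys = np.array([schedule.camps[i][1] for i in camp_idx])
    elev = np.array([schedule.camps[i][2] for i in camp_idx])
    sr = isoscape.mean.lookup(xs, ys)
    d18o = p["mean"] + p["amplitude"] * np.sin(
        2 * np.pi * (time - p["phase_day"]) / schedule.year_length
    )
    d13c = em.enamel_from_elevation(elev, is_archaeological=False)
    return EnvironmentSeries(time=time, sr_ratio=sr, d18O=d18o, d13C_enamel=d13c, elevation=elev)


def record_tooth(
    env: EnvironmentSeries,
    timing: ToothTiming,
    maturation_window_days: float = 180.0,
    n_samples: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    isotope: str = "Sr",
    tooth_id: str = "synthetic",
) -> IsotopeProfile:
    """Record one isotope system into an intra-tooth profile.

    The recorded value at each crown position is the rectangular-kernel
    mean of the environmental series over the maturation window starting
    at that position's formation age (see :mod:`toothtrack.recording`),
    plus Gaussian analytical noise of SD ``noise_sd``.
    """
    series = env.series(isotope)
    distances, recorded = sample_tooth(
        env.time, series, timing, maturation_window_days, n_samples
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        recorded = recorded + rng.normal(0.0, noise_sd, recorded.shape)
    return IsotopeProfile(
        tooth_id=tooth_id,
        isotope=isotope,
        distance_mm=distances,
        value=recorded,
        sd=np.full(distances.shape, float(noise_sd)),
        metadata={
            "tooth_label": timing.tooth_label,
            "maturation_window_days": maturation_window_days,
            "noise_sd": noise_sd,
        },
    )


def synthetic_curve(
    cal_lo: float,
    cal_hi: float,
    wiggle_amp: float = 0.0,
    wiggle_period: float = 200.0,
    sigma: float = 10.0,
    step: float = 1.0,
    identity: bool = True,
):
    """A synthetic calibration curve over ``[cal_lo, cal_hi]`` cal BP.

    With ``wiggle_amp == 0`` the curve mean is the identity mu(theta) =
    theta; otherwise a sinusoidal wiggle of the given amplitude and
    period (years) is superimposed.  ``sigma`` is the (constant) curve
    uncertainty.
    """
    from .chronology import CalibrationCurve

    grid = np.arange(cal_lo, cal_hi + step / 2, step)
    mu = grid.astype(float).copy()
    if not identity:
        raise ValueError("only identity-based synthetic curves are supported")
    if wiggle_amp:
        mu = mu + wiggle_amp * np.sin(2 * np.pi * grid / wiggle_period)
    sd = np.full(grid.shape, float(sigma))
    if np.any(sd < 0):
        raise ValueError("curve sigma must be non-negative")
    return CalibrationCurve(cal_bp=grid, mu=mu, sigma=sd)


def make_radiocarbon_dataset(
    true_start_calBP: float,
    true_end_calBP: float,
    n_dates: int,
    curve,
    errors,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Draw radiocarbon dates from a known uniform occupation phase.

    Calendar dates are uniform on ``[true_end, true_start]`` (cal BP
    decreases toward the present); each measured BP age is the curve mean
    at the date plus Gaussian noise with variance
    ``sigma_curve**2 + sigma_lab**2``.  Returns ``(bp_age, sigma_lab)``
    pairs.
    """
    if true_start_calBP <= true_end_calBP:
        raise ValueError("phase start must be older (larger cal BP) than its end")
    if curve.cal_bp[0] > true_end_calBP or curve.cal_bp[-1] < true_start_calBP:
        raise ValueError("calibration curve does not cover the phase")
    errors = np.broadcast_to(np.asarray(errors, dtype=float), (n_dates,))
    rng = np.random.default_rng(seed)
    thetas = rng.uniform(true_end_calBP, true_start_calBP, n_dates)
    mu, sig_curve = curve.interp(thetas)
    total_sd = np.sqrt(sig_curve**2 + errors**2)
    bp = mu + rng.normal(0.0, 1.0, n_dates) * total_sd
    return [(float(b), float(s)) for b, s in zip(bp, errors)]
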