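"""Seasonal anchoring, the d13C-elevation chain, and relocation counting.

d18O in enamel tracks meteoric water and oscillates annually (high in
summer, low in winter), so a sinusoid fitted to the d18O profile anchors
the crown in seasonal time.  Enamel d13C is inverted to feeding elevation
through a calibrated linear diet-elevation relation for the Altai region:
enamel is first shifted by the Suess correction (archaeological samples
only), then by the diet-enamel fractionation, and the resulting diet
d13C is mapped through

    d13C_diet = a * elevation + b,    a = -1.45e-3 per-mil/m, b = -24.14 per-mil

Elevation uncertainty is propagated by Monte Carlo over the calibration
coefficients.  Relocations are counted by exact penalized change-point
segmentation (PELT) of the smoothed Sr profile, converted to a per-year
rate with the d18O anchor's period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .profiles import IsotopeProfile

__all__ = [
    "ElevationModel",
    "ElevationEstimate",
    "SeasonalAnchor",
    "enamel_to_elevation",
    "fit_seasonal_anchor",
    "profile_amplitude",
    "count_relocations",
    "pelt_segment",
]


@dataclass
class ElevationModel:
    """Coefficients of the diet d13C - elevation relation and the
    corrections linking enamel to diet.

    ``slope``/``intercept`` (with standard errors) define
    d13C_diet = slope * elevation + intercept.  ``suess_shift`` is added
    to archaeological enamel to undo the industrial-era atmospheric d13C
    decline; ``diet_enamel_fractionation`` is added to (corrected) enamel
    to recover diet.  Elevations below ``plausible_floor_m`` are flagged
    implausible for the Altai setting rather than clipped.
    """

    slope: float = -1.45e-3          # per-mil per metre
    slope_se: float = 3.07e-4
    intercept: float = -24.14        # per-mil
    intercept_se: float = 0.71
    suess_shift: float = -2.0        # per-mil, archaeological only
    diet_enamel_fractionation: float = -13.7  # per-mil, enamel -> diet
    plausible_floor_m: float = 1500.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("slope must be negative: plant d13C decreases with elevation")

    def diet_from_enamel(self, d13c_enamel, is_archaeological: bool = True):
        d13c_enamel = np.asarray(d13c_enamel, dtype=float)
        suess = self.suess_shift if is_archaeological else 0.0
        return d13c_enamel + suess + self.diet_enamel_fractionation

    def elevation_from_diet(self, d13c_diet):
        return (np.asarray(d13c_diet, dtype=float) - self.intercept) / self.slope

    def diet_from_elevation(self, elevation_m):
        return self.slope * np.asarray(elevation_m, dtype=float) + self.intercept

    def enamel_from_elevation(self, elevation_m, is_archaeological: bool = False):
        """Forward chain used by the simulator: elevation -> diet -> enamel."""
        suess = self.suess_shift if is_archaeological else 0.0
        return self.diet_from_elevation(elevation_m) - self.diet_enamel_fractionation - suess


@dataclass
class ElevationEstimate:
    """Per-sample elevation with Monte-Carlo uncertainty and plausibility."""

    elevation_m: np.ndarray
    sd_m: np.ndarray
    ci_low_m: np.ndarray
    ci_high_m: np.ndarray
    implausible: np.ndarray  # True where below the plausible floor


def enamel_to_elevation(
    d13c_enamel,
    model: ElevationModel | None = None,
    is_archaeological: bool = True,
    n_mc: int = 10_000,
    seed: int = 0,
) -> ElevationEstimate:
    """Invert enamel d13C to feeding elevation with uncertainty.

    The point estimate uses the central coefficients; the uncertainty is
    a seeded Monte Carlo over Gaussian draws of slope and intercept
    (their quoted standard errors are large, so first-order propagation
    would understate the spread).  95% CIs are percentile-based.
    """
    model = model or ElevationModel()
    d13c_enamel = np.atleast_1d(np.asarray(d13c_enamel, dtype=float))
    diet = model.diet_from_enamel(d13c_enamel, is_archaeological)
    point = model.elevation_from_diet(diet)
    rng = np.random.default_rng(seed)
    a = rng.normal(model.slope, model.slope_se, n_mc)
    b = rng.normal(model.intercept, model.intercept_se, n_mc)
    # (n_mc, n_samples)
    draws = (diet[None, :] - b[:, None]) / a[:, None]
    sd = draws.std(axis=0, ddof=1)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return ElevationEstimate(
        elevation_m=point,
        sd_m=sd,
        ci_low_m=lo,
        ci_high_m=hi,
        implausible=point < model.plausible_floor_m,
    )


@dataclass
class SeasonalAnchor:
    """Fitted annual sinusoid of a d18O profile, in crown distance units.

    ``period_mm`` converts crown distance to fractions of a year;
    ``n_years`` is the number of annual cycles the profile spans.
    """

    amplitude: float
    period_mm: float
    phase_mm: float
    mean: float
    n_years: float
    peaks_mm: np.ndarray
    troughs_mm: np.ndarray
    residual_sd: float
    degenerate: bool = False

    def predict(self, distance_mm):
        d = np.asarray(distance_mm, dtype=float)
        return self.mean + self.amplitude * np.sin(
            2 * np.pi * (d - self.phase_mm) / self.period_mm
        )


def _sinusoid(d, mean, amp, period, phase):
    return mean + amp * np.sin(2 * np.pi * (d - phase) / period)


def fit_seasonal_anchor(profile: IsotopeProfile, min_samples: int = 8) -> SeasonalAnchor:
    """Fit an annual sinusoid to a d18O profile by nonlinear least squares.

    Multiple starting periods (fractions of the profile span) are tried
    and the best fit kept; peak/trough positions come from the fitted
    curve.  If the fitted amplitude is indistinguishable from noise
    (< 2x residual SD) the anchor is flagged degenerate and should not be
    used for per-year rates.
    """
    if len(profile) < min_samples:
        raise ValueError(f"need at least {min_samples} samples to fit a seasonal anchor")
    d = profile.distance_mm.astype(float)
    v = profile.value.astype(float)
    span = d.max() - d.min()
    amp0 = (v.max() - v.min()) / 2.0
    mean0 = float(v.mean())
    if amp0 == 0 or span == 0:
        return SeasonalAnchor(0.0, max(span, 1.0), 0.0, mean0, 0.0,
                              np.array([]), np.array([]), 0.0, degenerate=True)
    best = None
    for frac in (0.33, 0.5, 0.75, 1.0, 1.5, 2.0):
        p0 = [mean0, amp0, span * frac, d.min()]
        try:
            popt, _ = curve_fit(
                _sinusoid, d, v, p0=p0, maxfev=20_000,
                bounds=([-np.inf, 0.0, span * 0.05, -np.inf],
                        [np.inf, np.inf, span * 6.0, np.inf]),
            )
        except RuntimeError:
            continue
        resid = v - _sinusoid(d, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("sinusoid fit failed to converge for all starting periods")
    sse, (mean, amp, period, phase) = best
    dof = max(len(v) - 4, 1)
    resid_sd = float(np.sqrt(sse / dof))
    degenerate = amp < 2.0 * resid_sd
    # peaks at phase + period/4 (mod period), troughs at phase + 3*period/4
    peaks, troughs = [], []
    k0 = int(np.floor((d.min() - phase) / period)) - 1
    k1 = int(np.ceil((d.max() - phase) / period)) + 1
    for k in range(k0, k1 + 1):
        p = phase + (0.25 + k) * period
        t = phase + (0.75 + k) * period
        if d.min() <= p <= d.max():
            peaks.append(p)
        if d.min() <= t <= d.max():
            troughs.append(t)
    return SeasonalAnchor(
        amplitude=float(amp),
        period_mm=float(period),
        phase_mm=float(phase),
        mean=float(mean),
        n_years=float(span / period),
        peaks_mm=np.sort(np.array(peaks)),
        troughs_mm=np.sort(np.array(troughs)),
        residual_sd=resid_sd,
        degenerate=bool(degenerate),
    )


def profile_amplitude(values) -> float:
    """Observed range (max - min) of a profile's values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two samples for an amplitude")
    return float(values.max() - values.min())


def pelt_segment(values: np.ndarray, penalty: float, min_size: int = 5) -> list[int]:
    """Exact penalized change-point search with squared-error cost (PELT).

    Minimizes sum of within-segment squared deviations plus
    ``penalty * n_changepoints``.  Returns the sorted interior
    change-point indices (each index is the first sample of a new
    segment).  Pruning keeps the search exact while close to linear-time
    in favourable regimes.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_size:
        raise ValueError(f"profile shorter than twice the minimum segment length ({min_size})")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(s, t):
        # cost of segment x[s:t] (vectorized over array s)
        nlen = t - s
        total = c1[t] - c1[s]
        return (c2[t] - c2[s]) - total * total / nlen

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        mature = (t - candidates) >= min_size
        cand = candidates[mature]
        if cand.size == 0:
            continue
        costs = F[cand] + seg_cost(cand, t) + penalty
        best = int(np.argmin(costs))
        F[t] = costs[best]
        last[t] = cand[best]
        # PELT pruning applies only to mature candidates; candidates not
        # yet eligible (segment would be too short) must be retained
        keep = F[cand] + seg_cost(cand, t) <= F[t]
        candidates = np.concatenate([cand[keep], candidates[~mature], [t]])
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(int(s))
        t = s
    return sorted(cps)


@dataclass
class RelocationCount:
    """Segmentation of a smoothed Sr profile into residence plateaus."""

    changepoints: list[int]
    segments: list[tuple[float, float, float]]  # (start_mm, end_mm, mean ratio)
    n_relocations: int
    relocations_per_year: float | None
    penalty: float


def count_relocations(
    sr_profile: IsotopeProfile,
    anchor: SeasonalAnchor | None = None,
    penalty: float | None = None,
    min_size: int = 5,
) -> RelocationCount:
    """Count residence changes in a smoothed Sr profile.

    Fits a piecewise-constant model by penalized exact change-point
    search; each boundary is a relocation.  The default penalty is
    BIC-like, ``c * sigma^2 * log(n)`` with the noise scale estimated
    robustly from first differences; because smoothing correlates
    neighbouring samples over roughly the smoothing window, the
    difference-based scale is corrected by the effective window length
    (metadata ``smoothed_window_n`` when present).  When a seasonal
    anchor is supplied, the per-year rate divides the count by the number
    of d18O years the profile spans.
    """
    v = sr_profile.value.astype(float)
    n = v.size
    if penalty is None:
        w = int(sr_profile.metadata.get("smoothed_window_n", 1))
        diffs = np.diff(v)
        if diffs.size == 0:
            raise ValueError("profile too short to segment")
        # MAD-based SD of the underlying (pre-smoothing) noise on the
        # smoothed series: differencing a w-point moving average scales
        # white noise by sqrt(2/w), so undo sqrt(2) and re-apply 1/sqrt(w).
        mad = np.median(np.abs(diffs - np.median(diffs)))
        sigma_diff = mad / 0.67449
        sigma = sigma_diff / np.sqrt(2.0) * np.sqrt(w)
        sigma = max(sigma, 1e-12)
        penalty = 2.0 * sigma**2 * np.log(n) * max(w, 1)
    cps = pelt_segment(v, penalty=penalty, min_size=min_size)
    bounds = [0, *cps, n]
    d = sr_profile.distance_mm
    segments = [
        (float(d[s]), float(d[e - 1]), float(v[s:e].mean()))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]
    n_reloc = len(cps)
    rate = None
    if anchor is not None and not anchor.degenerate and anchor.n_years > 0:
        rate = n_reloc / anchor.n_years
    return RelocationCount(
        changepoints=cps,
        segments=segments,
        n_relocations=n_reloc,
        relocations_per_year=rate,
        penalty=float(penalty),
    )
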