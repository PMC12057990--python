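"""Intra-tooth isotope profiles: containers, LA-MC-ICP-MS reduction,
smoothing, and inter-individual comparison.

Laser-ablation Sr transects arrive as raw ion-beam intensities on masses
88..83.  Reduction proceeds in the standard order: strip isobaric
interferences (87Rb via mass 85, Kr at masses 84/86 via mass 83), form the
87Sr/86Sr ratio, normalize by standard-sample-standard bracketing against
a certified reference material, then smooth with a centered moving average
(window of 35 measurements, ~2 mm of crown) with a matching rolling SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)

#: IUPAC natural isotopic abundance ratios used to strip interferences.
#: 87Rb/85Rb = 27.83/72.17; 86Kr/83Kr = 17.279/11.500; 84Kr/83Kr = 56.987/11.500.
NATURAL_RATIOS = {
    "rb87_rb85": 0.27835 / 0.72165,
    "kr86_kr83": 17.279 / 11.500,
    "kr84_kr83": 56.987 / 11.500,
}

#: TIMS certified 87Sr/86Sr of the NIST SRM-1400 bone-ash bracketing standard.
SRM1400_CERTIFIED = 0.71308

_DELTA_RANGE = (-30.0, 5.0)
_SR_RANGE = (0.70, 0.74)


@dataclass
class IsotopeProfile:
    """Ordered per-tooth series of (distance from ERJ, value[, SD]).

    ``isotope`` is one of ``d13C``, ``d18O`` (both per mil V-PDB) or
    ``Sr`` (dimensionless 87Sr/86Sr).  Distances are mm from the
    enamel-root junction and must be strictly monotonic; formation age
    decreases with increasing distance (older enamel toward the apex).
    """

    tooth_id: str
    isotope: str
    distance_mm: np.ndarray
    value: np.ndarray
    sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.isotope not in ("d13C", "d18O", "Sr"):
            raise ValueError(f"unknown isotope system {self.isotope!r}")
        if self.distance_mm.shape != self.value.shape or self.distance_mm.ndim != 1:
            raise ValueError("distance and value must be equal-length 1-D arrays")
        diffs = np.diff(self.distance_mm)
        if self.distance_mm.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("distances must be strictly monotonic")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.value.shape:
                raise ValueError("sd must match value shape")

    def __len__(self) -> int:
        return self.value.size

    def plausible(self) -> np.ndarray:
        """Boolean mask of values inside the physically plausible range."""
        lo, hi = _SR_RANGE if self.isotope == "Sr" else _DELTA_RANGE
        return (self.value > lo) & (self.value < hi)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"distance_mm_from_ERJ": self.distance_mm, "value": self.value}
        )
        df["sd"] = self.sd if self.sd is not None else np.nan
        return df

    def to_csv(self, path) -> None:
        import json

        df = self.to_frame()
        df.insert(0, "isotope", self.isotope)
        df.insert(0, "tooth_id", self.tooth_id)
        with open(path, "w") as fh:
            if self.metadata:
                fh.write(f"# metadata: {json.dumps(self.metadata)}\n")
            df.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "IsotopeProfile":
        import json

        metadata: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# metadata:"):
                metadata = json.loads(first.split(":", 1)[1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        sd = df["sd"].to_numpy() if "sd" in df and df["sd"].notna().any() else None
        return cls(
            tooth_id=str(df["tooth_id"].iloc[0]),
            isotope=str(df["isotope"].iloc[0]),
            distance_mm=df["distance_mm_from_ERJ"].to_numpy(),
            value=df["value"].to_numpy(),
            sd=sd,
            metadata=metadata,
        )


@dataclass
class LaserTransect:
    """Raw LA-MC-ICP-MS transect: per-point position and Faraday-cup
    intensities (volts) for masses 88, 87, 86, 85, 84 and 83, plus
    bracketing-standard measurements as (sequence position, measured
    87Sr/86Sr) pairs.  Sample points occupy sequence positions 0..n-1.
    """

    position_mm: np.ndarray
    intensities: dict[int, np.ndarray]
    standards: list[tuple[float, float]] = field(default_factory=list)
    tooth_id: str = ""

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        n = self.position_mm.size
        for mass in (88, 87, 86, 85, 84, 83):
            if mass not in self.intensities:
                raise ValueError(f"missing intensity channel for mass {mass}")
            arr = np.asarray(self.intensities[mass], dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"mass {mass} channel length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"negative intensity on mass {mass}")
            self.intensities[mass] = arr


def correct_interferences(
    transect: LaserTransect, natural_ratios: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Strip Rb and Kr isobaric interferences and form raw 87Sr/86Sr.

    Mass 85 is pure Rb and mass 83 pure Kr, so the interfering signals are
    87Rb = 85Rb * (87Rb/85Rb), 86Kr = 83Kr * (86Kr/83Kr) and
    84Kr = 83Kr * (84Kr/83Kr).  Returns ``(ratio, valid)`` where points
    whose corrected mass-86 signal is non-positive are flagged invalid
    (NaN ratio) and must be excluded downstream.
    """
    nr = dict(NATURAL_RATIOS)
    if natural_ratios:
        nr.update(natural_ratios)
    i87 = transect.intensities[87] - transect.intensities[85] * nr["rb87_rb85"]
    i86 = transect.intensities[86] - transect.intensities[83] * nr["kr86_kr83"]
    valid = i86 > 0
    ratio = np.full(i86.shape, np.nan)
    ratio[valid] = i87[valid] / i86[valid]
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("%d transect point(s) with non-positive corrected 86Sr flagged invalid", n_bad)
    return ratio, valid


def bracket_normalize(
    raw_ratios: np.ndarray,
    standards: list[tuple[float, float]],
    certified_value: float = SRM1400_CERTIFIED,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Standard-sample-standard bracketing correction.

    For each sample point the measured standard value is linearly
    interpolated between the preceding and following bracketing standards
    (by sequence position); the correction factor is
    ``certified / interpolated`` and is applied multiplicatively.  Points
    without a flanking standard on one side fall back to the nearest
    standard, with a warning.
    """
    raw = np.asarray(raw_ratios, dtype=float)
    if len(standards) < 2:
        raise ValueError("need at least two bracketing standards to interpolate between")
    pos = np.arange(raw.size, dtype=float) if positions is None else np.asarray(positions, float)
    spos = np.array([p for p, _ in standards], dtype=float)
    sval = np.array([v for _, v in standards], dtype=float)
    order = np.argsort(spos)
    spos, sval = spos[order], sval[order]
    unflanked = (pos < spos[0]) | (pos > spos[-1])
    if np.any(unflanked):
        warnings.warn(
            f"{int(unflanked.sum())} point(s) lack a flanking bracketing standard; "
            "using nearest standard",
            stacklevel=2,
        )
    interp_std = np.interp(pos, spos, sval)  # np.interp clamps == nearest fallback
    factor = certified_value / interp_std
    return raw * factor


def rolling_smooth(profile: IsotopeProfile, window_n: int = 35) -> IsotopeProfile:
    """Centered moving average and rolling SD over ``window_n`` points.

    Even windows are widened to the next odd size so the window is
    symmetric.  Windows are truncated (shrunk) at the profile ends rather
    than dropped: discarding half a window per end would throw away
    several mm of crown record.  The rolling SD mirrors the mean's
    truncation.
    """
    if len(profile) == 0:
        raise ValueError("cannot smooth an empty profile")
    if window_n < 1:
        raise ValueError("window must be positive")
    if window_n % 2 == 0:
        window_n += 1
    s = pd.Series(profile.value)
    roll = s.rolling(window=window_n, center=True, min_periods=1)
    mean = roll.mean().to_numpy()
    sd = roll.std(ddof=1).fillna(0.0).to_numpy()
    return IsotopeProfile(
        tooth_id=profile.tooth_id,
        isotope=profile.isotope,
        distance_mm=profile.distance_mm.copy(),
        value=mean,
        sd=sd,
        metadata={**profile.metadata, "smoothed_window_n": window_n},
    )


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    excluded: list[str]


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """Compare per-individual value distributions.

    ``groups`` maps individual/tooth labels to 1-D value arrays.  Groups
    with fewer than two values are excluded with a warning.  Returns the
    F statistic with its degrees of freedom and the Tukey HSD table of
    adjusted pairwise differences at the given alpha.
    """
    clean: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            excluded.append(name)
            warnings.warn(f"group {name!r} has <2 values; excluded", stacklevel=2)
        else:
            clean[name] = vals
    if len(clean) < 2:
        raise ValueError("need at least two groups with >=2 values each")
    f_stat, p_val = stats.f_oneway(*clean.values())
    values = np.concatenate(list(clean.values()))
    labels = np.concatenate([[name] * v.size for name, v in clean.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    k = len(clean)
    n = values.size
    return GroupComparison(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p_val),
        tukey=tukey_df,
        excluded=excluded,
    )
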