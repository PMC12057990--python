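#!/usr/bin/env python
"""Forward validation: GPS track + isoscape vs the measured tooth.

Annotates the daily GPS track of the first individual with isoscape
ratios, runs the recording kernel over the residence-weighted series to
predict its M2 Sr profile, and compares the prediction with the
measured (smoothed) profile - the consistency check between movement
data and the enamel record.
"""

from pathlib import Path

from toothtrack.forward import Track, annotate_track, compare_profiles, predict_profile
from toothtrack.grids import Isoscape
from toothtrack.profiles import IsotopeProfile
from toothtrack.recording import TOOTH_TIMINGS

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    iso = Isoscape.read(SIM / "isoscape_mean.asc", SIM / "isoscape_sd.asc")
    track = Track.from_csv(SIM / "track.csv")
    ann = annotate_track(track, iso)
    print(f"{ann.t_days.size} fixes annotated, {ann.n_excluded} excluded, "
          f"{len(ann.gaps)} gap(s)")
    t, v = ann.to_series()
    pred = predict_profile(t, v, TOOTH_TIMINGS["M2"],
                           maturation_window_days=60.0, n_samples=200)
    pred.to_csv(OUT / "forward_predicted_Sr.csv")
    measured = IsotopeProfile.from_csv(next(iter(sorted(OUT.glob("smoothed_Sr_*.csv")))))
    res = compare_profiles(pred, measured)
    print(f"prediction vs measured profile: RMSE {res['rmse']:.5f}, "
          f"bias {res['bias']:+.5f}, Spearman rho {res['spearman']:.2f} "
          f"over {res['overlap_mm'][0]:.0f}-{res['overlap_mm'][1]:.0f} mm")


if __name__ == "__main__":
    main()
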