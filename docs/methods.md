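# Methods

This note documents the models implemented in `toothtrack`, their
assumptions, the parameters that matter, and the design choices made
where the underlying methodology left the design open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Tooth recording model

Enamel at a given crown position does not snapshot its environment: the
maturation of enamel spreads mineral uptake over weeks to months, so the
recorded isotope value is a low-pass-filtered version of the
environmental input. We model this with a **rectangular kernel**: the
value recorded at a position with nominal formation age *t* is the mean
of the environmental series over [*t*, *t* + Δ], where Δ is the
maturation window.

- `maturation_window_days` (default **180 d**; recovery experiments and
  the bundled synthetic study use **60 d**). Published data for horse
  molars give only the total integration span of each crown (M1 ≈ 1.9 y,
  M2 ≈ 2.5 y, M3 ≈ 2.8 y), not a kernel shape or width; the rectangular
  shape is the simplest consistent with averaging, and the width is a
  free parameter. The 60-day value used for laser-ablation work reflects
  that the inner enamel layer — the zone such transects target —
  mineralizes early and fast, limiting signal attenuation; 180 days is a
  conservative default for bulk drilled samples.
- Crown geometry is a **linear distance–time mapping**: the apex forms
  at the start age, the ERJ at the end age. Real crown extension
  decelerates, but no growth-curve model is available for these teeth;
  linearity keeps the timing model invertible and transparent.
- Default mineralization timings (months, ±1σ): M1 0.5 ± 1 → 23 ± 3,
  M2 7 ± 1.5 → 37 ± 3, M3 21 ± 3 → 55 ± 2; crown lengths 60/70/80 mm
  (typical unworn values).

The kernel is implemented once (`toothtrack.recording`) and shared by
the simulator (`record_tooth`) and the forward model
(`predict_profile`); a divergence between the two is a test failure.
With a piecewise-linear cumulative integral, a step input produces an
exactly linear ramp of temporal extent Δ and a sinusoid of period *P* is
attenuated by |sin(πΔ/P)/(πΔ/P)| — both are tested against closed forms.

## Laser-ablation signal reduction

Masses 88–83 are reduced in the standard order: ⁸⁷Rb stripped using the
interference-free ⁸⁵Rb channel, Kr at masses 86 and 84 stripped using
⁸³Kr, ratio formed, then standard–sample–standard bracketing against
sintered NIST SRM-1400 (certified ⁸⁷Sr/⁸⁶Sr 0.71308). Natural-abundance
constants are configuration, not code: ⁸⁷Rb/⁸⁵Rb = 0.27835/0.72165,
⁸⁶Kr/⁸³Kr = 17.279/11.5, ⁸⁴Kr/⁸³Kr = 56.987/11.5 (IUPAC abundances).
Points whose Kr-corrected mass-86 signal is non-positive are flagged
invalid and excluded. The bracketing factor is
certified / (position-interpolated measured standard); points without a
flanking standard fall back to the nearest one with a warning. No
exponential mass-bias law is applied: bracketing is the only
normalization beyond interference stripping, and an optional
⁸⁸Sr/⁸⁶Sr internal normalization is deliberately left out of the default
path.

Smoothing uses a **centered moving average over 35 measurements**
(~2 mm of crown at typical laser feed rates) with a matching rolling SD.
Edge windows are truncated (shrunk) rather than dropped: discarding 17
points per end would throw away several millimetres of crown record.
The rolling SD mirrors the mean's truncation.

## Isoscape model

Bioavailable ⁸⁷Sr/⁸⁶Sr is regressed on gridded covariates with a random
forest:

1. covariates are sampled at each site by nearest-cell lookup (rasters
   are the resolution authority; no interpolation);
2. covariates with |Pearson r| > 0.9 are removed by an order-stable
   greedy rule (the later-listed member of each offending pair drops);
3. predictors are selected by permutation importance scored on a held
   30 % split, thresholded against an appended pure-noise feature plus a
   1 % -of-top-importance floor (held-out scoring keeps overfit
   irrelevant features near zero importance; the floor guards against
   ties with the noise probe);
4. the forest (default 3000 trees, `min_samples_leaf` 5) is evaluated by
   ten-fold site-random cross-validation, reporting RMSE and % variance
   explained (1 − MSE/Var);
5. the SD surface is derived from a quantile regression forest in the
   Meinshausen sense — per-query weights over training responses from
   leaf co-occupancy — as half the width of the central 68.27 %
   prediction interval, floored at 10⁻⁶ to keep the layer strictly
   positive. Under homoscedastic Gaussian noise this half-width
   estimates the noise σ, which is the calibration the tests check.

CV folds are site-random, not spatially blocked: with spatially
autocorrelated real covariates this overstates transfer skill, a known
limitation shared by the approach this package follows.

## Geographic assignment

For a smoothed profile value *m* with rolling SD *s*, the likelihood at
cell *i* is the normal density of *m* under mean μᵢ and variance
σᵢ² + s² (isoscape uncertainty and sample uncertainty in quadrature);
the posterior is this likelihood normalized over the valid cells of a
square area of interest under a uniform prior. Design points:

- **"Top 10 % of the area"** is an *area* threshold: cells are ranked by
  posterior and the smallest prefix reaching 10 % of the valid-cell
  count is taken, ties broken by flat cell index. It is not a 10 %
  probability-mass contour.
- Nested scales default to **100/200/400 km** boxes centered on the
  site; boxes partially outside the grid are clipped, fully-outside
  scales are skipped with a warning.
- Profile features (peaks, troughs, plateaus) are picked automatically
  as local extrema of the smoothed profile with prominence ≥ 0.0005
  (ratio units) — an operationalization of what is otherwise a by-eye
  choice; a profile whose total range is below the prominence is treated
  as a single plateau.
- The **local/non-local call** is a 2σ envelope rule: an individual is
  non-local if any feature value falls outside
  [min(μ − 2σ), max(μ + 2σ)] over cells within 50 km of the site. The
  rationale string attached to every call states that this is an
  operational criterion, not a map-inspection judgement.

On grids up to 10×10 the posterior and mask are verified against an
independent brute-force implementation to 10⁻¹².

## Seasonality, elevation, relocations

**δ¹⁸O anchor.** A sinusoid (mean, amplitude, period in crown mm,
phase) is fitted by nonlinear least squares from several starting
periods; the number of years covered is span/period. If the fitted
amplitude is below twice the residual SD the anchor is flagged
degenerate and per-year rates are not derived from it.

**δ¹³C → elevation.** The chain is: archaeological enamel is shifted by
the Suess correction (−2 ‰; modern samples skip it, as the calibration
is against modern plants), then by the diet–enamel fractionation
(−13.7 ‰), and the resulting diet δ¹³C is inverted through
δ¹³C_diet = a·E + b with a = −1.45·10⁻³ ± 3.07·10⁻⁴ ‰/m and
b = −24.14 ± 0.71 ‰. Uncertainty is propagated by seeded Monte Carlo
over Gaussian draws of (a, b) (default 10 000 draws) because the quoted
standard errors are too large for first-order propagation to be honest.
Elevations below 1500 m are *flagged* implausible for a high-mountain
setting, never clipped: the inversion is treated as an indicator of
altitudinal movement, not a calibrated altimeter.

**Relocation counting.** The smoothed Sr profile is segmented into a
piecewise-constant model by exact penalized change-point search (PELT,
squared-error cost, minimum segment length 5 samples); each boundary is
a relocation, and the per-year rate divides the count by the anchor's
years. The default penalty is BIC-like, 2σ̂² log n, with two
corrections for the fact that the input is *smoothed*: the noise scale
σ̂ is recovered from the MAD of first differences undone for the
w-point averaging (differencing a w-point moving average scales white
noise by √(2/w)), and the penalty is multiplied by w because the series
carries only n/w independent samples. The penalty constant was fixed by
the synthetic two-patch design (patches 0.002 apart, analytical noise
0.0005) before being frozen; the segmentation-count-vs-penalty
monotonicity is a tested invariant.

## Radiocarbon chronology

**Calibration** evaluates the posterior density
∝ exp(−(bp − μ(θ))² / 2(σ² + σ_curve(θ)²)) on a 1-year calendar grid
spanning the curve (linear interpolation between knots), normalized by
trapezoidal integration. If more than 10⁻³ of the mass sits in the
outermost cells the curve is rejected as too narrow. HPD regions use
the highest-density-cells construction; the reporting level is 95.4 %
(the 2σ convention). Quality control retains a collagen sample iff its
atomic C/N is within [3.1, 3.3] **or** its extraction yield is ≥ 5 %;
samples with neither measurement are indeterminate and excluded.

**Phase model.** The N dates' calendar positions θᵢ are uniform within
an occupation interval [β, α] (cal BP; α = start). The likelihood
therefore carries a (α − β)⁻ᴺ factor, which is what prevents the phase
from spreading gratuitously; the prior on the boundaries themselves is
flat over the curve support, with the span floored at one grid step to
keep the zero-span corner of the posterior proper. An explicit extra
1/(α − β) prior factor was implemented and rejected during development:
it collapses the span posterior hard enough that nominal-level HPD
intervals stop covering simulated truth, whereas the flat-prior form is
calibrated on simulation (the coverage study is part of the acceptance
checks). All full conditionals are exactly sampleable — θᵢ by
inverse-CDF draws from its calibrated density truncated to [β, α], each
boundary by the analytic inverse CDF of its power-law gap density — so
the sampler is plain Gibbs: 4 chains × 25 000 draws by default, 20 %
burn-in, with a split-R̂ ≤ 1.1 gate that raises on failure. Calendar
conversion uses the 1950 CE datum with no year zero: cal BCE =
cal BP − 1949 (2991 cal BP = 1042 cal BCE, unit-tested).

## Forward model

GPS fixes are annotated with isoscape ratios by nearest-cell lookup
(half-open cell convention: a point on a shared edge belongs to the
east/north cell). Fixes are **residence samples weighted by inter-fix
duration**: the annotated series holds each ratio until the next fix
before resampling to days, so irregular collar schedules do not bias
the profile toward burst-sampled places. Prediction then runs the
shared recording kernel, noise-free, and requires full coverage of the
formation window — a coverage gap raises with the missing interval
rather than silently extrapolating. Comparison statistics (RMSE, mean
bias, Spearman rank correlation) are computed after linear resampling
of both profiles onto a common 200-point grid over their distance
overlap.

## Synthetic data: what it emulates, what it does not

The generator produces: isoscapes as smooth background fields
(Gaussian-filtered noise, default correlation length 6 cells) spanning
the central 60 % of the configured ratio range with discrete elliptical
lithological patches drawn over the full range, and an SD layer of
±50 % around `sd_level`; quarterly-round movement schedules; daily
environmental series (isoscape ratio at the occupied camp, sinusoidal
δ¹⁸O with defaults mean −12.8 ‰, amplitude 2.45 ‰ — a 4.9 ‰ annual
range — and a day-120 phase; enamel δ¹³C from camp elevation through
the forward elevation chain); tooth profiles through the recording
kernel with Gaussian analytical noise (defaults: 0.0005 for
laser-ablation Sr at 700 points/crown, 0.3 ‰ for drilled δ values at 40
samples/crown); and radiocarbon dates uniform in a configured phase
with noise √(σ_curve² + σ_lab²) on a synthetic identity-plus-wiggle
curve. Every generator is a pure function of its seed.

Deliberately not modelled: body-water/blood turnover physiology and
amelogenesis histology (the rectangular kernel stands in for all of
it), water-to-enamel δ¹⁸O transfer (δ¹⁸O is simulated directly in
enamel ‰ since only its phase anchors the analysis), crown growth
deceleration, diagenesis, foddering, and real covariate structure
(lithological age maps, climate rasters). Tests passing on synthetic
data therefore demonstrate the *inference machinery* — not that real
enamel chemistry is this clean. In particular the relocation-recovery
rate holds under the stated synthetic conditions (patches ≥ 0.002
apart, noise ≤ 0.0005, quarterly moves); movements through isotopically
homogeneous terrain are invisible in principle, and the bundled study
reproduces that failure mode when two camps share similar cells.

## Numerical choices and degenerate inputs

- Even smoothing windows are widened to the next odd size; empty
  profiles are rejected.
- Constant responses are rejected by the isoscape fit (variance
  explained undefined); constant covariates are dropped with a warning.
- Posterior normalization is done in log space; an all-invalid
  assignment box raises.
- The sinusoid fit tries six starting periods and keeps the best SSE;
  a fit failure across all starts raises rather than returning a
  silent default.
- Radiocarbon curves are stored ascending regardless of input order;
  descending files are normalized on read.
- Sub-seeds for nested generators are drawn below 2³¹ from a parent
  `numpy` Generator, so every stage is reproducible from one integer.

## Problem sizes

The test suite and acceptance script run deliberately scaled-down
studies chosen to exercise every code path with stable statistics:
48×48 or smaller grids, 400–500 training sites, 300–500 trees,
50-replicate recovery studies, and 100-replicate phase-coverage runs at
6 000 draws × 4 chains. The defaults embedded in the API (3000 trees,
25 000 draws) are the sizes a real study would use.
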