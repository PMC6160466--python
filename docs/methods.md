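# Methods

This note records the models, the numerical choices, and what the synthetic
study conditions do and do not establish.

## Data model

All series are one channel per animal with strictly increasing UTC
timestamps and no imputation: every downstream statistic uses only present
values. Channels and nominal cadences: activity proportion, head-movement
count, collar temperature and rumen temperature every 180 s; one set of
inter-beat intervals per 1260 s; NDVI as 16-day composites. Analysis
windows are half-open `[start, end)`, anchored at the study start (Nov 15),
so a record on a boundary belongs to the later window. Days are UTC
calendar days; local solar time enters only through longitude inside the
solar module.

## Sensor quality control

The in-rumen acceleration sensor is blind for 0.5 s after each detected
beat, which caps detectable heart rate at 60/0.5 = 120 bpm; rates are
represented as per-gap instantaneous rates 60/interval, never as counts.
The four filter steps run in fixed order and only remove, never alter:

1. **Coverage** — a window is kept iff its intervals sum to ≥ 70% of
   180 s (the boundary itself is kept).
2. **Activity** — the activity cutoff is the kernel-density minimum between
   the two highest modes of the whole-deployment activity distribution
   (Gaussian kernel, Silverman bandwidth, 512-point grid on [0, 1]); a
   window is kept iff concurrent activity ≤ cutoff, and discarded when no
   activity record exists within 90 s (conservative).
3. **Modal rate** — kernel density of the window's rates on a 512-point
   grid over [20, 120] bpm; mode returned, absent below 5 intervals.
4. **Trend outliers** — a least-squares cubic regression spline over the
   deployment, interior knots every 10/15/20 days with the spacing chosen
   by GCV (capping flexibility near one effective df per 10 days so the
   trend cannot chase contamination spikes); points with residual strictly
   above +30 or strictly below −20 bpm are removed, the boundary values
   kept. Single pass.

Rumen temperature: a record is dropped iff it differs by more than 0.25 °C
from the **last retained** record, so a whole drinking dip (and its
recovery ramp) is removed until the temperature returns to within 0.25 °C
of the pre-dip level. Records on either side of a data gap are still
compared; rumen temperature moves slowly enough that this costs < 0.1% of
clean records at the default noise.

## Lomb–Scargle rhythm detection

Linear trends are removed first (ordinary least squares on time), then the
classical periodogram with the per-frequency time offset is computed
(via `scipy.signal.lombscargle`) and divided by twice the sample variance
of the detrended series. With that normalization each power is Exp(1)
under a white-noise null, and the identity

    normalized power = (explained SS of the best-fit sinusoid at that
                        frequency, on centered values) / (2 · variance)

holds to machine precision — the test suite checks it against an
independent `lstsq` fit at random frequencies to 1e−8 relative.

**Grid and significance.** Periods are spaced evenly in frequency with
M = ceil(ofac · T · Δf) + 1 points for window length T and band width Δf;
the p-value of a peak is p = 1 − (1 − e^(−z))^M with the same M. These two
choices interlock: the Sidak-style correction is exact only when the M
scanned powers are independent, which is true near ofac = 1 and
increasingly false as the grid oversamples. The default **ofac = 2** keeps
M close to the effective number of independent trials: the measured type-I
error of the 15-day, 21–27 h band minimum-p test at nominal 0.05 is ≈ 0.04
(it would fall to ≈ 0.03 at ofac = 4, i.e. the test would go conservative).
The grid step near 24 h is then ≈ 0.8 h for 15-day windows and ≤ 0.2 h for
season-long scans, which is what the entrainment tolerance needs.

**Windowed power** (15-day windows, 21–27 h) averages the power of
significant (p < 0.05) local maxima only; a window with none contributes an
absent value, not a zero — seasonal averages are means over detected
rhythms. Windows must cover at least ten cycles of the longest band period.
**Season classification** scans each photic-season segment (skipping
segments shorter than ten cycles) and labels it entrained when the
strongest significant peak lies within 24 ± 0.25 h, free-running when
significant peaks exist but the strongest is off-24, arrhythmic otherwise.
Peak periods are read off the grid; no sub-grid interpolation or phase
estimation is attempted.

## Solar geometry and photic seasons

Declination and the equation of time come from the Spencer Fourier series
with the **calendar day-of-year phase** — the convention of the standard
zenith-angle routines used in this literature. That phase carries a known
equinox declination bias of up to ~0.5° against a modern ephemeris (the
test suite bounds the difference at 0.6°), and it is deliberate: at 78.33°N
it is exactly what places the continual-civil-daylight span at Apr 5 –
Sep 7/8 (day-of-year 95–250/251); an astronomically corrected phase moves
the onset two days earlier. Elevation is geometric (no refraction), civil
twilight is the centre of the disk at −6° exactly. Direct beam irradiance
is 1.353 · 0.7^(AM^0.678) kW/m² with Kasten–Young air mass (finite at the
horizon), zero at or below the horizon; daily variance is the population
variance over a 180-s grid (600 s where only day labels are needed — the
labels are insensitive to the grid).

A day is DD when max elevation < −6°, LL when min elevation ≥ −6°, else
LD. Consecutive labels merge into segments; the LL run splits at the first
date the fitted NDVI curve exceeds zero (LL_low → LL_high). If the NDVI
curve never goes positive the whole span stays LL_low with a warning. The
computed DD onset at the site is Nov 13–14 (the module never hard-codes a
date); default site coordinates are 78.0°N 16.0°E, with 78.33°N (the
area's northern boundary) used for the calendar-date checks.

## Annual baseline-cosine model

y(t) = b + H · (1 + cos(2π·d/(w·T)))/2 inside |d| ≤ w·T/2, else b, with d
the circular distance from the acrophase and T = 365.25 d. Onset and
offset are the window edges, where the curve meets the baseline
continuously. Fitting is unweighted nonlinear least squares on daily
means: multi-start over w ∈ {0.2, 0.4, 0.6} with t_peak initialised at the
30-day rolling-mean argmax, b at the 10th percentile, H at the range;
bounds H ≥ 0, w ∈ [0.02, 1]. The baseline is declared real only when
freeing w beats the plain full-year cosine (w = 1) in an
extra-sum-of-squares F-test at α = 0.05; the degenerate flag blocks the
derived summaries (pct increase = 100·H/b, rise = w·T/2, duration = w·T).
Uncertainty is a parametric bootstrap (default 500 resamples, seeded):
Gaussian noise at the residual SD around the fitted curve, refits started
from the point estimate, percentile 95% intervals for parameters and for
the derived onset/offset dates (acrophase draws are unwrapped onto the
point estimate's branch). The NDVI curve uses the same model on ≥ 20
composites; its daily-resolution zero crossing feeds the season split and
the driver covariate.

## Mixed model of diel power drivers

One row per animal × 15-day window with significant diel power: response
ln(mean significant 21–27 h power); covariates the window means of daily
radiation variance, daily collar-temperature variance and the fitted NDVI
curve. Response and covariates are z-scored over the analysis sample, so
coefficients are standardized betas. The REML random-intercept fit is
delegated to `statsmodels.MixedLM` (cross-checked against lme4 in the test
suite); a boundary fit is reported with zero between-animal variance and a
warning rather than raised. Each predictor gets a Wald F = (β/se)² with
df (1, n − 3 − 1) — the denominator rule is pinned and documented rather
than matched to any particular software convention. The natural log is
used; only signs and relative sizes of betas are interpreted.

## Synthetic study conditions

The generator is the package's study design, not a tuning knob. Defaults:
three animals, Nov 15 2012 – Nov 15 2013, site 78.0°N 16.0°E. Annual
profiles use the baseline-cosine form itself (closed loop with the
fitting stage): stationary heart rate b = 40 bpm, H = 50.4 (+126% in
65 d, acrophase day 197); rumen temperature +2% in 77 d; mean activity
+39% in 140 d; head movements +101% in 65 d; collar temperature −15 °C
winter to +5 °C summer; NDVI from −0.1 to +0.6 crossing zero in early
June. The diel component is entrained (τ = 24 h) in LD and LL and
free-running at τ = 23.4 h in DD, with phase kept continuous across
season boundaries; amplitude is attenuated ×0.4 in DD and LL_high and
additionally coupled log-linearly (betas +0.25/−0.25) to the z-scored
daily radiation variance and NDVI, giving the driver stage a recoverable
truth. Ultradian components run at 6 h (winter) and 4 h (peak
vegetation). Activity is emitted by modulating the probability of the
active state and drawing from two Beta modes near 0.02 and 0.97, so the
marginal is bimodal as the classifier requires. Beat windows draw
n ≈ 180·coverage/(60/HR) intervals of mean 60/HR with 0.03 s jitter,
floored at the 0.5-s dead time — the 120-bpm ceiling is mechanistic, not
clipped.

No per-channel signal-to-noise figures exist for this sensor system, so
noise levels were fixed once at values a field deployment of this hardware
would plausibly show (activity probability noise 0.05; collar 0.8 °C; rumen
0.05 °C; heart-rate process noise 1 bpm; NDVI composite noise 0.02) and
kept: they make LD-window diel detection near-certain while leaving the
×0.4-attenuated DD windows detectable. Artifacts at default rates, every
one labelled: 4 drinking dips/day (depth 1.5–2.5 °C, 15-min core plus
exponential recovery), 15% of beat windows motion-corrupted (20% of
intervals replaced by 2–4 s gaps), 8% of windows with failed UHF coverage,
+50 bpm contamination spikes on 5% of the windows that reach the trend
filter, 10% record dropout. Collar temperature gets a day-level weather
factor on its diel range so its daily variance is informative but not a
proxy for the radiation/NDVI coupling; because the ×0.4 DD attenuation is
a season effect not fully carried by the two coupled covariates, the
collar-temperature term can pick up part of that contrast in closed-loop
fits — its coefficient is deliberately unconstrained in the recovery
checks. Randomness is one `default_rng([seed, animal_index])` stream per
animal, so individuals are independently reproducible.

## What the validation runs show (and their sizes)

`reinrhythm.validation` backs both the acceptance tests and
`scripts/acceptance.py`; chosen problem sizes: significance calibration on
1000 white-noise 15-day windows; period recovery at τ ∈ {23.2, 24.0,
25.5} h over 100 replicates each at the rumen channel's default
signal-to-noise and dropout; QC recovery on a 60-day single-animal
deployment; bootstrap-CI coverage over 100 replicates of 365 daily means
(noise SD 3 bpm, 500 resamples each); mixed-model recovery over 100
replicates of 200 rows with true betas (0.5, 0, −0.7), intercept SD 0.3,
noise SD 0.5; the closed loop on one full 3-animal study year.

Passing these establishes internal consistency — the pipeline recovers
what the generator injected under realistic noise — not field validity.
Real deployments add features the generator omits: weather in both collar
temperature and radiation exposure, behavioural autocorrelation beyond the
rhythmic components, sensor drift and battery decline (handled in the
field by manual date masks, here by a config mask), pregnancy/body-mass
effects between animals, and NDVI retrieval artifacts. Printed results
derived from the original field data (specific dates, confidence
intervals, Table-style coefficients) are not reproducible from synthetic
data; what is reproduced is the structure: year-round rhythmicity,
free-running Polar Night, entrained Midnight Sun, vegetation-season
attenuation, and the sign pattern of the drivers.

## Known limitations

* Peak periods are grid-limited; no sub-grid refinement, no phase.
* The Sidak-style band correction is tied to the default oversampling;
  user-chosen ofac ≫ 2 makes the min-p test conservative.
* The Step-4 trend is a single-pass fit; extreme contamination fractions
  (≫ 5%) would bias it upward and erode spike removal.
* `MixedLM` provides no Satterthwaite/Kenward-Roger df; the pinned rule is
  a convention, adequate at these sample sizes.
* Solar geometry targets calendar-date fidelity over astronomical accuracy
  (see above); do not reuse it where sub-0.1° elevations matter.
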