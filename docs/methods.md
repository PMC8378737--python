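# Methods

This note documents the models, numerical conventions and design
choices behind `echosat`, and what the synthetic-data tests do and do
not demonstrate about real survey data.

## Data model and units

An `Echogram` is a ping × depth matrix of volume backscattering
strength S_V (dB re 1 m⁻¹) on a uniform depth grid (metres below the
sea surface, transducer offset assumed applied upstream), with per-ping
UTC time and position.  One sentinel (NaN) marks missing data
everywhere in the package; a sample thresholded to zero energy during
integration is *not* missing — removed noise is excluded from means,
low backscatter is counted as ~0 energy.  Any averaging that crosses
the dB boundary is done on the linear coefficient s_v = 10^(S_V/10),
because energy, not decibels, is additive.  Vertical resampling
(default: 1000 bins over 0–750 m, i.e. 0.75 m) weights source samples
by their overlap fraction with each target bin, which removes any
dependence on grid phase and conserves layer-integrated linear energy
for nested grids.

## Denoising

Stages run in a fixed order — background → impulsive → transient →
attenuated → validity — and are deterministic.

*Background.* Time-varied gain TVG(r) = 20 log₁₀ r + 2αr (α is the
seawater absorption for the frequency; defaults 2.6–53 dB/km from 18 to
200 kHz; r floored at 1 m) is removed, power is averaged in the linear
domain over cells of 10 pings × 20 samples, and the per-ping-block
noise estimate is the minimum over depth cells, capped at −125 dB.
Noise is re-amplified by TVG and subtracted in the linear domain;
samples whose corrected SNR falls below 10 dB are masked.  The cell
size and cap follow common practice for this estimator and are
configurable; only the 10 dB SNR threshold is treated as fixed.

*Impulsive.* A sample is masked when it deviates by ≥ 10 dB *in the
same direction* from the same-depth samples of both adjacent pings;
edge pings are compared to their single neighbour.  Sample-level
masking was chosen over whole-ping removal because a deep clean sample
should survive a shallow spike.

*Transient.* A sample more than 10 dB above the median (configurable
percentile) of its surrounding 5-ping × 9-sample window — centre
excluded, windows truncated at edges — is *replaced* by that context
value and flagged.  Replacement rather than removal keeps the domain
intact while removing the burst energy.

*Attenuated.* A ping whose linear-domain band mean is ≥ 10 dB below the
pooled band means of the 3 preceding and 3 following pings is masked
entirely.  The band defaults to the frequency's full valid depth range.

*Validity.* Depths beyond 500/275/150 m are removed at 70/120/200 kHz;
the top 10 m (bubble/ringdown zone) is removed at all frequencies.

## Seafloor

The bottom on each ping is the shallowest vertical-median-smoothed
(5 samples) local maximum deeper than 20 m whose S_V reaches −30 dB; no
qualifying peak means no bottom, and `BottomLine.fill_gaps()`
interpolates such pings between neighbouring picks (no extrapolation),
the usual line-editing practice for pings whose seabed echo is
suppressed, e.g. by attenuation.  The pipeline picks the line on the
*raw* echogram: the seabed peak is tens of dB above any water-column
scatterer, whereas the transient filter can clip the echo's upper flank
where neighbouring pings are attenuated.  One line (38 kHz by default)
is shared across co-registered frequencies.  Everything at or below
(bottom − 5 m) is excluded from integration.

## Echo integration

NASC = 4π·1852² · mean(s_v over valid samples) · (n·Δz) per 4 km
along-track bin × depth layer, with the −80 dB threshold zeroing (not
removing) faint samples.  Using the grid-covered thickness n·Δz makes
the four layers exactly additive against a single 10–750 m layer; with
the 0.75 m grid the nominal layer thicknesses are reproduced to ~1%.
Cells with under 10% valid samples (configurable) are reported missing.
Along-track bins follow cumulative great-circle distance on a 6371 km
sphere (haversine; < 0.3% error) — deliberately *not* snapped to the
satellite grid, mirroring the known misalignment between track-based
and grid-based aggregation.  The day/night flag uses a standard
low-precision solar ephemeris (declination + equation of time,
accuracy ≪ 0.5°) at the bin midpoint; day is strictly elevation > 0.

## Satellite matchup

Terra and Aqua scenes of the same day are averaged cellwise ignoring
missing; daily merges are averaged over a ±3-day window (missing only
if missing on all 7 days); the window mean is sampled at the bin
midpoint by nearest cell — no interpolation, matching the 4 km-to-4 km
aggregation scale.  Distance from shore is the minimum spherical
cross-track distance to the coastline polylines; ocean depth is
bilinear in the bathymetry raster (positive down).  Feature rows with
missing NASC, NASC ≤ 0 (log undefined), or any missing satellite
covariate are dropped, each with its own counter, and the three
counters reconcile exactly with the output row count.

## Models and evaluation

Both variants are 100-tree regression forests on log_e NASC with
minimum terminal-node size 5 and unlimited depth; mtry defaults to 1/3
of the features (the standard regression-forest default; exposed in
`ModelSpec`).  Categorical covariates (frequency, depth layer, their
interaction) are one-hot encoded.  The frequency × depth-layer
interaction is an observation covariate and appears in *both* variants,
so the full-vs-reduced contrast isolates exactly the four satellite
variables.  Latitude folds are equal-width bands over the observed
range (boundary rows go to the higher band, the maximum to the top
band); folds, seeds and rows are shared between variants, verified by
fingerprinting the training sets.  R² uses the plain
1 − SSE/SST definition with negatives reported as 0 alongside the raw
value; subgroups with n < 2 or constant response are reported missing,
not zero.  The withheld-year evaluation reports per-subgroup bias
(mean prediction − mean truth, log units).

## Synthetic surveys

The generator emulates a boustrophedon transect survey off a meridian
coastline: 10 east–west transects across 44–47.6°N, 28 km long, 5.1 m/s,
one ping per 1.1 s, four survey years.  Scattering is two Gaussian-in-
depth layers over a −88 dB diffuse floor: a "krill-like" layer (day
70 m / night 20 m, σ = 10 m, strongest at 120–200 kHz) whose amplitude
scales with a biomass field, and a "fish-like" layer (day 340 m / night
250 m, σ = 30 m, strongest at 18–38 kHz).  Layer centres follow a
logistic function of solar elevation (width 3°), so diel vertical
migration is smooth through twilight.  The seafloor deepens offshore
(110 m shelf + 22 m/km), producing a −15 dB echo (σ = 1 m) with a
decaying sub-bottom reverberation tail (−18 dB, 1.5 dB/m).  Background
noise is TVG-shaped from a per-frequency floor (−162 … −140 dB at 1 m);
it is deterministic by default (`noise_sd_db = 0`), which makes the
background-subtraction oracle exact — an idealization relative to real
receiver noise.

The biomass field is a sum of latitudinal harmonics (wavelengths
0.5/0.3/0.2°, amplitudes 0.45/0.35/0.25 in log space) with
year-specific phases plus a longitudinal term, analytically detrended
in latitude so it shares no linear structure with the satellite fields'
deterministic gradients — a mesoscale-anomaly construction that makes
the zero-link case genuinely uninformative.  Satellite fields are
deterministic functions of latitude and (scaled by the link strength)
of that biomass field, plus noise (σ_log = 0.15 for chl/POC, 0.3 °C for
SST) and 15% missing cells per platform-day.  The anomaly-year scenario
adds +1.5 log units of shallow biomass, +2 °C of SST and −0.3 log units
of chlorophyll — a strong covariate-shift stand-in for a marine
heat-wave year, sized so the extrapolation-bias phenomenon is
unambiguous at desk scale.

Injected artifacts carry exported ground-truth masks: impulsive spikes
(+15 dB, single samples at rate 2·10⁻⁴ of eligible samples), transient
blobs (+15 dB, 2 pings × 15 samples, 0.01/ping), and attenuated runs
(−20 dB over 2–3 consecutive pings, 1% of pings — isolated attenuated
pings would be consumed by the upstream impulsive test, and real
bubble sweep-down spans several pings).  Injection is restricted to
"eligible" samples: inside the frequency's validity range, ≥ 15 dB
above the noise, and clear of the seafloor echo — artifacts placed
where the background stage deterministically masks them would be
unrecoverable by construction, and filter scores are computed against
these labels.

## Problem sizes

The echogram-level checks run on single short transects (≈ 360 pings ×
1000 depth bins); filter recovery aggregates 20 simulation seeds and
bottom detection 3.  The modelling study uses the analytic route —
tracks binned to 4 km cells, closed-form clean-field NASC (Gaussian
integrals, truncated at the bottom exclusion) with 0.5-log-unit
lognormal observation error, then the real matchup and evaluation code
— giving ≈ 3.9k feature rows across four years per seed and 10 seeds
for each finding.  These sizes were chosen so the full test suite runs
on a single core in about ten minutes; rendering ping-level echograms
for the multi-year, multi-seed modelling study would add nothing to
what the small-scale echogram tests already verify.

## What passing tests do and do not show

The simulator has Gaussian layers, smooth fields, deterministic noise
and labelled artifacts; real echograms have species-dependent target
strength, patchiness, weather-dependent noise and unlabelled artifact
mixtures.  Passing recovery tests therefore demonstrates that the
implementations honour their contracts at the stated thresholds, not
that those thresholds are optimal at sea.  Likewise the full-vs-reduced
R² gap measures information flow through the pipeline under a
*configured* biomass–ocean-colour link, not the strength of any real
ecological coupling.

## Known limitations

No calibration-gain handling, broadband/pulse-compressed data, beam
geometry or dead-zone correction; bottom backstep is vertical (no slope
compensation); satellite scenes have no quality flags or sensor drift;
zero-NASC cells are excluded from the log-scale models (counted and
logged); the CLI's demo-scale config defaults are much smaller than the
generator's survey defaults.
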