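# echosat

Can satellite ocean-colour data predict what a ship's echosounder sees
below the surface?  `echosat` is a desk-scale, fully tested pipeline for
answering that question: it takes multi-frequency water-column echograms
(ping × depth rasters of volume backscattering strength, S_V) from
acoustic transect surveys, denoises them, integrates them into the
nautical area scattering coefficient (NASC, a standard biomass proxy),
matches each 4 km cell to satellite covariates (chlorophyll-a,
normalized fluorescence line height, particulate organic carbon, SST),
and evaluates whether those covariates add predictive skill under
spatially and temporally blocked holdouts.  A synthetic survey generator
with exported ground truth makes every stage verifiable without any
external data download.

It is written for fisheries-acoustics and marine-ecology researchers who
want a transparent, scriptable version of the Echoview-style processing
chain plus the downstream statistical evaluation.

## The method

**Echo integration.** S_V (dB re 1 m⁻¹) is converted to the linear
coefficient s_v = 10^(S_V/10); all averaging happens in the linear
domain.  For a depth layer of thickness Δz, each 4 km along-track bin ×
frequency cell gets

    NASC = 4π · 1852² · mean(s_v) · Δz   [m² nmi⁻²]

with samples below −80 dB contributing zero energy (thresholded, not
missing) and masked samples excluded from the mean.  Layers are
10–50 m ("shallow"), 50–200 m ("mid"), 200–500 m ("shelf") and
500–750 m ("deep"), restricted per frequency to its usable depth
(70 kHz ≤ 500 m, 120 kHz ≤ 275 m, 200 kHz ≤ 150 m).

**Denoising.** Five stages in fixed order: (1) background-noise
subtraction with a minimum-cell noise estimate under time-varied gain
(20 log₁₀ r + 2αr) and a 10 dB SNR threshold; (2) impulsive spikes —
samples ≥ 10 dB above or below both adjacent pings; (3) transient
bursts — samples > 10 dB above the median of their 5-ping × 9-sample
context, adjusted to that median; (4) attenuated pings — whole pings
≥ 10 dB below the pooled band mean of 3 pings either side; (5)
frequency–depth validity cutoffs.  The seabed is picked per ping as the
shallowest smoothed peak ≥ −30 dB and excluded together with a 5 m
backstep.

**Modelling.** Two 100-tree regression forests (minimum node size 5,
unlimited depth) predict log_e NASC: a *reduced* model using only
geographic/observation covariates (daytime, distance from shore,
frequency, depth layer, their interaction, latitude, ocean depth) and a
*full* model adding the four satellite covariates (7-day window means
of daily Terra/Aqua merges, nearest 4 km cell).  Skill is measured by
R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)² (negatives reported as 0) and Pearson r,
per frequency × depth-layer subgroup, under (a) 10-fold
cross-validation blocked by latitude band and (b) a withheld final
survey year.

## Worked example

Simulate one short night-time transect, denoise the 38 kHz echogram,
pick and exclude the seafloor, and integrate to NASC:

```python
from echosat import (SimConfig, simulate_cruise, simulate_echograms, denoise,
                     detect_bottom, mask_below_bottom, along_track_bins,
                     integrate_nasc)

cfg = SimConfig(seed=42, years=(2012,), n_transects=1,
                transect_length_km=4.0, start_hour_utc=8.0)
track = simulate_cruise(cfg)[2012]
echograms, truth = simulate_echograms(cfg, track)

cleaned, report = denoise(echograms[38])
print(report.to_frame().to_string(index=False))

line = detect_bottom(echograms[38]).fill_gaps()   # pick on raw Sv
cleaned, _ = mask_below_bottom(cleaned, line)
bins = along_track_bins(cleaned.latitudes, cleaned.longitudes)
cells = integrate_nasc(cleaned, bins, cruise_id="DEMO")
print(cells[["bin_index", "depth_layer", "daytime", "nasc",
             "valid_fraction"]].round(2).to_string(index=False))
```

Output:

```
     stage  samples_flagged  pings_flagged
background           486127            714
 impulsive               35             33
 transient              260             20
attenuated              715              4
  validity             9230            710
 bin_index depth_layer  daytime  nasc  valid_fraction
         0     shallow    False 11.32            0.99
         0         mid    False  4.87            0.85
         0       shelf    False   NaN            0.01
         0        deep    False   NaN            0.00
         1     shallow    False 10.53            1.00
         1         mid    False  7.04            1.00
         1       shelf    False   NaN            0.09
         1        deep    False   NaN            0.00
```

Reading it: the background stage removes the deep, low-SNR majority of
samples; the injected spikes, bursts and attenuated pings are flagged at
their injection rates.  At night the migrating scattering layer sits at
~20 m, so the shallow layer carries NASC ≈ 11 m² nmi⁻² while the shelf
and deep cells — almost entirely below the ~150–190 m seafloor here —
are reported missing (valid fraction below the 0.1 guard).

The same chain is available as a CLI
(`echosat simulate | denoise | integrate | matchup | fit | evaluate |
report`) driven by a YAML config whose defaults are the processing
parameters above; every run logs a parameter echo and per-stage
counters.

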