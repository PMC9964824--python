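# Methods

## Data model and quality control

All computation runs on `HourlyStationSeries`: one station's variables on a
complete local-time hourly grid with a per-value QC flag (`valid`,
`missing`, `out_of_range`, `gap_filled`). Values outside fixed plausibility
intervals (PM2.5/PM10 0–1000 µg m⁻³, NOx/SO2 0–1000 ppb, CO 0–100 ppm,
T −5–50 °C, RH 0–100 %, WS 0–50 m s⁻¹, WD 0–360°, rain 0–1000 mm h⁻¹,
GR 0–1000 W m⁻²) are masked before any statistic touches them; the
intervals are closed, so boundary values (RH = 100 %) are retained, and
WD = 360° is normalized to 0°. Screening is idempotent.

Wind uses the meteorological convention: `wd` is the direction the wind
blows *from*; components u = −ws·sin(wd), v = −ws·cos(wd) point where the
air moves. Donor-station wind gap-filling regresses u and v separately
(ordinary least squares on overlapping valid hours, minimum 48) rather than
speed/direction, because direction is circular and regressing it directly
creates wrap-around artifacts. Remaining interior gaps of ≤ 3 h are linearly
interpolated in component space; filled hours are flagged and
speed/direction recomputed. Valid values are never altered.

Daily means are taken over the valid hours of each local calendar day and
reported only when ≥ 75 % of the 24 hours are valid (18 h). The threshold
is a choice: low enough to keep realistic station records, high enough that
a daily mean cannot be dominated by one part of the diurnal cycle.

## Haze days, episodes, statistics

A haze day requires a *strict* exceedance (> 50 µg m⁻³) at ≥ 2 stations;
a day at exactly the threshold is not haze. Days with fewer than 2 valid
station means are non-haze and flagged data-poor. Episode segmentation
merges maximal haze runs separated by ≤ 2 non-haze days (configurable),
recording the gap days as bridged; episodes never start or end on a bridged
day. Merging is by gap length only — a further condition that the merged
runs share the same haze type would make segmentation depend on typing,
which depends on segmentation; we avoid the circularity.

Episode statistics (mean, sample n−1 SD, cv) are over the daily
cross-station mean PM2.5 of *all* span days, bridged included — episode
day counts then exceed haze day counts exactly as the bridging rule
implies. A single-day episode has SD = cv = 0 by convention. Days with no
valid station are dropped with a warning.

## Solar geometry

Sunrise/sunset come from the standard low-precision solar-position
equations (Fourier-series declination and equation of time, hour angle at
−0.833° apparent altitude). Accuracy is ±3 min against published
ephemerides, immaterial for hourly criteria windows, and removes any
dependence on a lookup service. Latitudes within 24° of the poles are
rejected rather than approximated.

## Sea-breeze classification

The four criteria are evaluated on hourly samples within windows anchored
to sunrise (SR) and sunset (SS):

* (a) offshore-or-calm strictly more than half of valid hours in
  [SR − 6 h, SR + 2 h];
* (b) ≥ 2 consecutive onshore hours in [SR + 2 h, SS + 2 h];
* (c) offshore-or-calm majority in [SS + 2 h, SS + 8 h];
* (d) mean land temperature between SR and SS minus daily SST > 3 °C
  (strict; exactly 3 °C fails).

"Majority" is strictly more than half of the *valid* hours; each window
needs ≥ 75 % valid wind hours, otherwise the day is unclassifiable and
excluded from downstream fractions and summaries. Calm is ws < 0.5 m s⁻¹
(the criteria leave "calm" to the analyst; 0.5 m s⁻¹ is the common
anemometer stall threshold). The criterion (c) window is anchored to sunset
on both ends; an alternative sunrise-anchored start would overlap the
criterion (b) window and make (b) and (c) mutually exclusive for long
breezes, so the sunset anchoring is the default and the window is exposed
in configuration.

Direction sectors are a property of the coastline and are configuration;
the defaults suit a coast south of the city — onshore (wind from sea)
135°–255°, offshore 315°–75°, coast normal pointing inland at 15°.

SB duration is the length of the longest consecutive onshore run in the
(b) window (first run on ties). Penetration is that run's cumulative
displacement projected on the inland coast normal, negative projections
clipped to zero, in km (Σ max(0, u·sin n + v·cos n)·3.6). This is the
plain wind-run estimate of how far the marine air travels inland; at
typical onshore speeds ~1 m s⁻¹ over ~8 h it gives the observed
tens-of-kilometres order.

## Recirculation factor

Over the daytime window 10:00–18:00 LT (nine hourly samples, ≥ 75 %
valid): X = T·Σuᵢ, Y = T·Σvᵢ, WR = T·Σ√(uᵢ² + vᵢ²), all in km with T = 1 h,
and RF = 1 − √(X² + Y²)/WR. The wind run is the summed hourly travel
distance — the only definition under which RF is a meaningful ratio
(summing √(X² + Y²) itself would make RF identically zero). RF is clamped
to [0, 1] against floating-point round-off at the bounds and reported
absent when WR = 0 (calm day) or too few hours are valid. RF is invariant
to frame rotation and uniform speed scaling.

## Episode typing

The narrative influence criteria become three explicit thresholds
(`TypingConfig`): a CS arrival counts if at least one CS day falls within
[start − 3 d, start + ⌈duration/2⌉ − 1] — the scan extends into the episode
because synergistic episodes sometimes show the surge *after* the breeze
phase; SB influence requires SB days on ≥ 1/3 of the episode span; a
Type II call with SB on fewer than half of the days carries a
low-confidence note. The four types partition episodes by the (CS, SB)
truth table, and the assignment is monotone: adding a CS day can only move
an episode II→III or IV→I, adding an SB day only I→III or IV→II.

Per-type summaries report mean ± SD over episode *days* (not episodes) of
PM2.5, temperature, RH, cloud cover, global radiation and RF, and over SB
days only for SB duration/penetration — absent for a type containing no SB
days.

## Precursor-ratio screening

Daily ratios are ratios of daytime means (06–18 LT inclusive, ≥ 75 % valid
hours per pollutant), not means of hourly ratios: the latter is unstable
whenever CO dips near zero for an hour. The clean baseline for an episode
is the mean ratio over DJF days of the episode's season year (November of
the previous calendar year through October defines the season year; the
DJF winter of season year N is Dec N−1 to Feb N) that are neither haze nor
episode days, requiring ≥ 10 such days.

The screening decision uses strict inequalities — a tie is "no change" —
with a relative tolerance of 1e-9 so that floating-point round-off in
otherwise identical ratios never counts as a change. A missing SO2 record
means so2_down is false and the category is decided on NOx alone.

The screen is deliberately a heuristic: it has no significance margin. When
an episode's precursor emissions are in fact unperturbed, its episodic mean
ratio differs from the clean baseline only by sampling noise, and the
strict comparison becomes a near-fair coin flip. Synthetic recovery
reflects this: with hourly noise off, planted secondary episodes are
identified exactly (flag accuracy 1.0); with default noise, unperturbed
episodes are flagged at roughly chance rate. Interpreting the flag on real
data therefore requires the same caution as in the screening literature.

## Synthetic scenarios

The generator emulates: a sinusoidal diurnal temperature (28 ± 4 °C,
afternoon peak) and RH cycle; mild offshore synoptic wind (2 m s⁻¹ from
30°); cold-surge events (2 windy days at 5 m s⁻¹ with a 4 °C/15 % T/RH
drop, then calm stagnation at 0.4 m s⁻¹); sea-breeze days (offshore night
at 0.6 m s⁻¹, a 7 h onshore run at 0.8 m s⁻¹ starting ~2 h after the
criterion (b) window opens, planted land−sea ΔT of 5 °C realised by setting
the day's SST from the generated daytime land temperature); and pollutant
dynamics by a first-order box model C(t+1) = C(t) + E − k_vent·ws·(C − bg)
floored at the background (bg = 20 µg m⁻³, E = 8 µg m⁻³ h⁻¹,
k_vent = 0.3 (m s⁻¹ h)⁻¹). These values bracket the 50 µg m⁻³ threshold
the way the observed winters do: steady state ≈ 33 µg m⁻³ under synoptic
wind, ≈ 87 µg m⁻³ under stagnation, ≈ 58 µg m⁻³ under a sea-breeze spell.
CO is co-emitted proportionally (0.015 ppm per µg m⁻³ over a 0.4 ppm
background), NOx and SO2 ride on CO (55 ppb/ppm, 2.5 ppb/ppm) with planted
depletions and a PM boost on secondary-episode days. Independent Gaussian
hourly noise per variable (PM 1.5 µg m⁻³, T 0.2 °C, ws 0.05 m s⁻¹,
direction jitter 0° by default) is added per station. Everything is driven
by one seeded generator; identical configs give bit-identical output.

Ground truth combines the planted calendars with haze structure derived
from the *noiseless* series through the same detection definitions, so a
perfect detector must score 1.0 by construction when noise is off. The
default scenario spans one 90-day winter and contains one episode of each
type plus one planted secondary perturbation.

What the generator does **not** emulate — and what passing recovery tests
therefore do not demonstrate about real data: synoptic variability beyond
the scripted events, rain washout, multi-day pollutant transport,
station-to-station meteorological heterogeneity (stations share one wind
field), diurnal emission cycles, and any real aerosol chemistry behind the
ratio perturbations.

## Problem sizes

The test suite and acceptance script use one 90-day, 5-station winter
scenario (plus a 14-day single-station scenario replicated 50 times for the
direction-jitter sensitivity study), 1000 random wind days for the
recirculation properties, and exhaustive enumeration of all haze calendars
up to 20 days against a brute-force segmentation oracle. These sizes make
the whole suite run in well under a minute while exercising every planted
structure.

## Known limitations

* Cold-surge days are consumed as a flag calendar; the synoptic-chart
  identification that produces them is upstream of this package.
* Episode re-splitting after typing (the "similar haze type" merge
  condition) is intentionally not performed; see segmentation above.
* SST arrives as a pre-averaged daily series; no reanalysis box-averaging
  is done here.
* The typing thresholds are judgment calls made explicit; sensitivity to
  them should be explored via `TypingConfig` on real data.
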