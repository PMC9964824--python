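# hazecoast

Haze-episode detection and coastal-meteorology attribution for hourly urban
air-quality station data, built around the winter (December–February) haze
record of Greater Bangkok but configurable for any coastal city with a
multi-station PM2.5 network.

## What it computes

Air-quality analysts studying coastal cities face a recurring question: when
PM2.5 builds up for days at a time, is the stagnation synoptic (a cold-surge
aftermath), local (sea-breeze recirculation under a thermal internal
boundary layer), both, or neither? This package turns that attribution into
a reproducible pipeline:

1. **Haze days and episodes.** A *haze day* is a calendar day whose 24 h
   mean PM2.5 strictly exceeds 50 µg m⁻³ at ≥ 2 stations. Consecutive haze
   days form an *episode*; two runs separated by ≤ 2 clean days are merged,
   the gap recorded as bridged. Episodes longer than 7 days are
   *persistent*. Each episode carries the mean, sample SD and coefficient of
   variation (cv = σ/µ) of the daily cross-station mean PM2.5.
2. **Sea-breeze (SB) days**, from surface winds and land–sea thermal
   contrast: (a) offshore-or-calm majority from 6 h before to 2 h after
   sunrise, (b) ≥ 2 consecutive onshore hours between sunrise + 2 h and
   sunset + 2 h, (c) offshore-or-calm majority in the post-breeze evening
   window, (d) daytime land mean T − daily SST > 3 °C. SB duration is the
   longest onshore run; penetration is its integrated inland displacement.
3. **Recirculation factor** over the 10:00–18:00 LT window,
   RF = 1 − √(X² + Y²)/WR with X = T·Σuᵢ, Y = T·Σvᵢ and wind run
   WR = T·Σ√(uᵢ² + vᵢ²): RF = 0 is straight-line transport, RF = 1 a closed
   loop.
4. **Episode typing** from a cold-surge (CS) day calendar and SB coverage:
   Type I = CS only, Type II = SB only, Type III = both, Type IV = neither.
5. **Secondary-aerosol screening** by CO-normalized precursor ratios:
   an episode whose daytime PM2.5/CO rises above the same-season clean-day
   baseline while NOx/CO and/or SO2/CO fall is flagged as potentially
   secondary-affected (sulfate+nitrate, nitrate-only, or sulfate-only).

A synthetic scenario generator (`hazecoast.synthetic`) plants cold surges,
sea-breeze days, haze buildups (first-order box-model dynamics) and
secondary perturbations with full ground-truth labels, so every stage is
testable without any observational download.

## Worked example

Generate the bundled default winter scenario (one season containing all
four episode types), run the full pipeline on it, and score the recovery:

```sh
hazecoast simulate --outdir demo --seed 42
hazecoast recover --scenario-dir demo
```

```json
{
 "sb_sensitivity": 1.0,
 "sb_specificity": 1.0,
 "haze_day_jaccard": 1.0,
 "haze_day_exact": 1.0,
 "episode_day_jaccard": 1.0,
 "type_accuracy": 1.0,
 "type_matched_episodes": 4,
 "secondary_flag_accuracy": 0.75
}
```

Every planted sea-breeze day, haze day and episode boundary was recovered,
and all four episode types were re-identified. The episode table produced by
the same run:

```
 episode_id      start        end  duration  haze_days  mean_pm25   sd_pm25       cv  persistent type
          1 2019-12-12 2019-12-15         4          4      81.47      9.92    0.122       False    I
          2 2020-01-05 2020-01-09         5          5      76.12      3.53    0.046       False   II
          3 2020-01-22 2020-01-27         6          6      71.84     11.34    0.158       False  III
          4 2020-02-10 2020-02-10         1          1      71.02      0.00    0.000       False   IV
```

Episode 1 is the cold-surge stagnation buildup (Type I), episode 2 the
sea-breeze spell carrying the planted secondary-aerosol perturbation
(Type II), episode 3 the surge-then-breeze synergy (Type III), and episode 4
an isolated emission-spike day (Type IV). `secondary_flag_accuracy` below 1
under default noise reflects the screening method itself: it compares means
with strict inequalities and no significance margin, so an unperturbed
episode's precursor ratios sit at a near-tie (see `docs/methods.md`).

For observational data, point a YAML config at your station CSVs, SST series
and cold-surge calendar and run `hazecoast report --config cfg.yml`; the
subcommands `detect`, `seabreeze`, `classify` and `ratios` run individual
stages.

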