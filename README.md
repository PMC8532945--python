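# stablegrid

Grid-based analysis of **area and resource utilization by group-housed
horses** tracked with GPS neck-collar loggers in an active (open) stable.

Active stables spread feeding, drinking and resting resources across a
paddock to stimulate movement. Given raw logger streams (one fix per
10 s: timestamps, latitude/longitude, height, speed, step distance),
`stablegrid` answers two questions a husbandry researcher asks of such a
farm:

1. **How much area does each horse use?** The farm is divided into a
   grid of 3 × 3 m squares and, for every horse-day, the number of
   *distinct squares visited per hour* is computed and modelled with a
   linear mixed model

   `y_ijkl = µ + B_i + S_j + D_k + A_l(B_i) + b·age_ijkl + e_ijkl`

   with fixed breed class `B` (warmblood / pony / other), sex `S`
   (gelding / mare), observation day `D`, age covariate `b`, and a
   random animal intercept `A` (variance σ²ₐ) nested in breed, estimated
   by REML. Fixed-effect structures are compared on ML fits with AICc in
   combination with BIC, added forward stepwise; least-square means are
   compared pairwise with Bonferroni adjustment at p < 0.05.

2. **Which places do the horses prefer?** Every square is labelled by
   the resource it belongs to (feed stalls FS_1–7, concentrate stalls
   CF_1–3, lying halls LH_1–3, straw racks RF_1–2, shelters SH_1–2,
   troughs TR_1–2, residual paddock, pasture). The percentage of a day's
   fixes falling in each square — the per-square *usage frequency* — is
   modelled as `y_ijk = µ + D_i + L_j + e_ijk` (OLS) and rendered as
   seasonal occupancy heatmaps with resource overlays.

Before gridding, raw streams pass a cleaning cascade: farm bounding-box
clip → sequential removal of physically impossible jumps (> 50 km/h or
> 140 m per 10 s, recomputed from coordinates against the last retained
fix) → clip to the paddock/pasture polygons. Days with fewer than 12 h
of recording (4320 fixes at 0.1 Hz) are excluded, separately for the
"with pasture" and "paddock only" dataset variants.

Because such farm datasets are typically not public, the package ships a
**behavioural herd simulator** (`synthetic_herd`): a semi-Markov state
machine (rest in a lying hall, feed, drink, stand, loiter, graze on the
open pasture during twice-daily ~90 min summer windows) with GPS noise,
teleport spikes, dropouts and a known ground truth — per-horse random
effects and an age effect acting on the state-switch rate — so the whole
pipeline, including parameter recovery by the mixed model, is testable
end to end.

## Worked example

```python
import stablegrid as sg

layout = sg.default_farm_layout(summer_days=8)
grid = sg.GridSpec.from_layout(layout)   # 3 m cells over paddock + pastures

cfg = sg.SimulationConfig(
    n_horses=8, n_days=10, summer_days=8, winter_days=2,
    n_newcomers=2, spike_prob=0.001, dropout_prob=0.02, rng_seed=11)
metas = sg.make_herd(cfg)
study = sg.simulate_study(metas, layout, cfg)

clean, report = sg.apply_filter_cascade(study.fixes, layout)
print(f"fixes kept {report.n_retained}/{report.n_input} "
      f"(bbox {report.removed_bbox}, step {report.removed_step}, "
      f"speed {report.removed_speed}, area {report.removed_outside_area})")

usage = sg.build_usage_table(clean, grid, layout)
included = usage[usage["included"]]
print(f"included horse-days: {len(included)}/{len(usage)}")
print(f"squares/h: {included['squares_per_hour'].mean():.1f} "
      f"+/- {included['squares_per_hour'].std():.1f}")

fit = sg.fit_model1(included, sg.metas_frame(metas))
b, se, p = fit.coef("age")
print(f"age slope: {b:.2f} +/- {se:.2f} squares/h per year (p = {p:.3f})")
print(f"animal variance: {fit.sigma_a2:.1f}, residual: {fit.sigma_e2:.1f}")

freq = sg.build_frequency_table(clean, grid, layout)
top = sg.location_usage(freq, layout, grid).sort_values(ascending=False)
print("busiest locations (% of daily fixes per square):")
print(top.head(4).round(3).to_string())
```

prints

```
fixes kept 586777/592752 (bbox 644, step 3, speed 0, area 5328)
included horse-days: 70/70
squares/h: 77.8 +/- 12.0
age slope: -0.59 +/- 0.21 squares/h per year (p = 0.007)
animal variance: 15.0, residual: 18.1
busiest locations (% of daily fixes per square):
LH_3    0.436
LH_2    0.375
CF_1    0.321
FS_2    0.319
```

Reading the numbers: the cascade removed the injected GPS spikes (bbox +
step rules) and the noise-displaced fixes outside the farm borders;
every horse-day carried at least 12 h of data; a horse occupied ~78
distinct 3 × 3 m squares per hour on average; mobility declined by ~0.6
squares/h per year of age (the value built into the simulator); and the
busiest squares sit in lying halls and feed stalls rather than on the
open paddock — exactly the resource-clustered picture the heatmaps show:

```sh
stablegrid heatmap square_day_frequency.csv --season summer --out heat_summer
```

The same pipeline is scriptable from the shell via the `stablegrid` CLI
(`simulate`, `ingest`, `filter`, `metrics`, `model`, `heatmap`; see
`stablegrid --help`).

## Layout of the code

| module | contents |
|---|---|
| `farm_geometry` | planar projection, farm layout (GeoJSON round-trip), 3 × 3 m grid, square→resource labelling |
| `synthetic_herd` | behavioural herd simulator with ground truth |
| `logger_io` | logger-CSV dialect, validation, horse-day splitting |
| `trajectory_filters` | bounding-box / speed / step / area cleaning cascade |
| `utilization_metrics` | squares-per-hour and usage-frequency responses, day inclusion |
| `mixed_models` | REML mixed model, OLS two-way model, AICc+BIC stepwise, LSM/Bonferroni |
| `heatmap_viz` | seasonal occupancy heatmaps |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
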