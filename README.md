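# vesselbird

Seabirds are attracted to fishing vessels by discards, but overlap maps
cannot tell whether an individual bird actually *interacted* with a vessel.
`vesselbird` implements a complete pipeline for detecting and quantifying
individual interactions between GPS/accelerometer-tracked central-place
foraging seabirds (the motivating system is Scopoli's shearwaters breeding
on a Mediterranean island) and GPS-monitored (VMS) fishing vessels:

1. **Ethogram** — 25 Hz tri-axial acceleration is turned into per-second
   behaviour labels. VeDBA (vectorial dynamic body acceleration,
   `VeDBA = sqrt(ax² + ay² + az²)` of the gravity-corrected components with
   1-s smoothing) identifies *sitting on the water* (0.1 g ≤ VeDBA ≤ 1 g at
   low ground speed); two-cluster spectral analysis of |Z| identifies
   *flapping flight*; short gaps between flapping bouts are *gliding*.
2. **VMS regularization** — native vessel pings (every 1–2 h) are linearly
   interpolated onto a shared 10-min grid and classified as steaming or
   fishing by gear-specific speed filters.
3. **Approach events** — each bird fix is joined with the single grid ping
   per vessel in a half-open ±5-min window; maximal runs of ≥2 consecutive
   fixes whose distance to one vessel strictly decreases by ≥500 m in
   total, starting within the 30-km attraction distance, are approaches.
4. **Interaction distance** — pooled bird–vessel pairs are binned (0.25 km)
   and each bin's mean percentage of sitting behaviour forms a distance
   profile; a continuous two-segment linear model fitted by profiling the
   breakpoint `ψ` over a fine grid (`y = β₀ + β₁·d + β₂·(d − ψ)₊`, minimum
   RSS, 95% CI by bootstrap over bins) estimates the distance below which
   birds switch to sitting at vessels.
5. **Validation & group statistics** — approaches reaching inside the
   interaction distance become interaction events; foraging trips are
   segmented at a colony radius and their metrics compared between
   interacting (INT-YES) and non-interacting (INT-NO) trips with linear
   mixed models (REML, random intercept per bird) and chi-square tests.

No tracking or VMS data are redistributable, so the package ships a
first-class synthetic-data generator (`vesselbird.simulate`) that emulates
all three data streams around a breeding colony with complete planted
ground truth — per-second behaviour, trips, vessel attendances and a known
true interaction distance — making every stage testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole synthetic study
(10 birds × 4 days, 12 vessels, seed 1) one stage at a time, writing
tables under `results/analysis/`:

```
$ python analysis/01_simulate.py
simulated 10 birds x 4.0 days with 12 vessels (seed 1)
  11520 GPS fixes, 771 native pings
  planted: 53 complete trips, 94 vessel attendances, 93 interaction events,
  true interaction distance 1.28 km

$ python analysis/02_ethogram.py
per-second agreement with planted labels: mean 99.31%, worst 98.51%

$ python analysis/03_vms_regularize.py
  fishing  :  4547 pings, interpolation error mean 0.08 km (p95 0.07)
  steaming :  1706 pings, interpolation error mean 2.73 km (p95 7.12)

$ python analysis/05_interactions.py
100425 bird-vessel pairs, 6919 approach runs
interaction distance: 1.25 km (95% CI 1.07-3.70; planted 1.28 km)
218 validated interaction events in 5 of 10 birds
```

The recovered interaction distance (1.25 km) lands within one 0.25-km bin
of the planted truth (1.28 km); exactly the scavenging half of the birds
produce validated events. `analysis/06_group_stats.py` then fits the four
mixed models (daily VeDBA sum, daily flight time, trip length, maximum
colony distance on sex × interaction status) and the chi-square tests on
trip records generated at the study's reported effect magnitudes.

The same pipeline is available as one command:

```
vesselbird run-all --seed 1 --out results/run
```

and stage by stage (`vesselbird simulate | ethogram | vms | trips |
interact | stats`) for use on real data files in the documented CSV
dialects.

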