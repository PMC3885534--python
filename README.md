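# aerosurvey

Toolkit for designing, geo-referencing and evaluating small fixed-wing RPAS
(remotely piloted aircraft system) surveys for wildlife protection —
originally motivated by rhinoceros anti-poaching patrols over South African
game farms, where a hand-launched ~2 kg aircraft with a still-photo, HD-video
or thermal-video payload flies lawnmower transects at 10–260 m AGL while
a 10 Hz GPS + barometric logger records the track.

It is written for conservation technologists and survey planners who need to
answer, before and after a flight:

* How much ground does one exposure cover, at what resolution, and how much
  do consecutive images overlap at a given altitude and speed?
* How many transects, how much flight time and how many sorties does a given
  farm polygon require, and is the mission feasible for the airframe?
* Where exactly was each image taken, what ground quadrilateral did it
  image, and was the whole target area actually covered?
* How do detection results break down by camera, habitat and time of day?

## The model

All imaging geometry follows from the pinhole camera. With sensor dimensions
`dv × dh` (mm), focal length `f` (mm), frame rate `P` (1/s), altitude `h`
(m AGL) and ground speed `S`:

* footprint: `L = (dv/f)·h` along track, `W = (dh/f)·h` across track
* along-track overlap: `O = 100·(1 − S_m/s / (P·(dv/f)·h))`, clamped to [0, 100)
* ground resolution: `R = c_res·h` (cm), linear in altitude
* coverage rate: `A = S_km/h·(dh/f)·h / 10` (ha/h)

Video cameras specified by a diagonal field of view get equivalent per-axis
constants from `2·tan(fov_axis/2)`, the diagonal split in pixel proportion.
On top of this sit a lawnmower planner (transect spacing
`swath·(1 − sidelap/100)`), a flight-log/event synchroniser with linear
position and circular course interpolation, a detection bookkeeping layer
(image-quality rubric, confirmed/not-confirmed rule, habitat and time-period
bins), and a fully seeded survey simulator that closes the loop without any
field data.

## Worked example

```
$ aerosurvey coverage --camera still_photo --agl 150 --speed 30 --area-ha 100000
camera             still_photo
agl_m              150.0
speed_kmh          30.0
overlap_pct        97.5
gsd_cm             6.81
footprint_along_m  164.7
swath_m            237.4
coverage_ha_per_h  712.1
time_to_cover_h    140.44
```

Flying the 11 MP still camera at 150 m AGL and 30 km/h images a 237 m swath
at ~6.8 cm ground resolution with 97.5 % forward overlap, covering about
712 ha per flight hour — so a 100,000 ha reserve takes ~140 gross flight
hours. Planning a 400 ha square farm:

```
$ aerosurvey plan --area farm.geojson --camera still_photo --agl 150 \
      --speed 30 --sidelap 20 --wind 10 --gcs=-28.19,31.96
transects=11 turns=10 path_km=24.61 time_min=49.2 sorties=1
check:wind=pass
check:altitude_band=pass
check:range=pass
check:endurance=pass
overall=pass
```

Eleven transects, 24.6 km of survey lines, 49 minutes — just inside the
airframe's 50 min endurance, at a safe wind and inside the recommended
100–180 m altitude band. `aerosurvey simulate` runs the same pipeline on a
synthetic landscape and `aerosurvey georef` / `aerosurvey summarize` process
the resulting (or real) flight logs and observations.

The library surface mirrors the CLI: see `aerosurvey.cameras`,
`aerosurvey.planning`, `aerosurvey.georef`, `aerosurvey.detections`,
`aerosurvey.simulate`, and `docs/methods.md` for the modelling details.

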