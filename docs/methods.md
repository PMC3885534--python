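# Methods

## Imaging geometry

All footprint, overlap, resolution and coverage relations derive from the
pinhole camera: a sensor of vertical × horizontal dimensions `dv × dh` mm
behind a lens of focal length `f` mm, aimed at the ground from altitude `h`
m AGL, images a ground rectangle `(dv/f)·h` along track by `(dh/f)·h` across
track. From this:

* **Along-track overlap.** Between exposures the aircraft advances
  `S/P` metres (ground speed `S` in m/s, frame rate `P` per second), so the
  overlap is `O = 100·(1 − S/(P·(dv/f)·h))` percent. It is clamped to
  `[0, 100)`: at `h = 0` the footprint is a point and the overlap is defined
  as 0 %, and an advance longer than the footprint reports 0 % rather than a
  negative number — coverage gaps are a planning quantity, not a property of
  an image pair. Overlap here is along-track only; across-track sidelap is a
  transect-spacing parameter of the planner, since frame rate and forward
  speed play no role in it.
* **Coverage rate.** A straight-flying camera sweeps its swath `(dh/f)·h`
  (m) at `S` km/h, i.e. `A = S·(dh/f)·h/10` ha per flight hour, exactly
  linear in both speed and altitude. Time-to-cover is gross strip-coverage
  time only; repositioning the ground station, turns, battery swaps and data
  processing are deliberately excluded (turns are counted separately by the
  planner).
* **Ground resolution.** Resolution is linear in altitude, `R = c_res·h`.
  For the built-in still-photo profile `c_res` is an empirically calibrated
  constant of 11.8/260 ≈ 0.0454 cm per metre AGL, anchored at the camera's
  measured 11.8 cm at 260 m; at 10 m it evaluates to 0.454 cm, which round
  figures elsewhere quote as 0.4 cm by truncation. For cameras without a
  calibrated constant the GSD falls back to footprint size over pixel count.
* **Field-of-view cameras.** Video cameras are specified by a diagonal field
  of view plus pixel counts. The diagonal is split per axis in pixel
  proportion on the tangent scale — `tan(fov_axis/2) =
  (px_axis/px_diag)·tan(fov_diag/2)` — which makes the per-axis GSD equal on
  both axes and recombines exactly to the specified diagonal.

Units at every interface: altitudes in metres AGL, speeds in km/h (converted
to m/s internally where the physics needs it), footprints in metres,
resolution in cm, areas in hectares.

The built-in profiles describe the three reference payloads: an 11 MP
still-photo camera (5.6 × 8.07 mm sensor, 5.1 mm focal length, 2 frames/s,
nadir in the wing), a 127° diagonal-FOV 1920×1080 HD video camera mounted
30° below the horizontal in the nose, and a 39.8° 640×480 thermal
microbolometer wing-mounted 15° off nadir. The still camera's horizontal
sensor dimension is taken as 8.07 mm, the effective wide-aspect width of its
1/1.63″ sensor class, which reproduces the reference 711 ha/h coverage figure
at 150 m and 30 km/h to better than 0.2 %. Two printed overlap extremes
(36.3 % and 99.2 %) cannot both be reproduced to the last digit by any single
`dv/f`; we keep the exact `5.6/5.1` and land at 36.8 % and 99.3 %, within
half a point of each.

## Transect planning

The survey polygon (GeoJSON, WGS84) is projected into a local spherical
transverse-Mercator frame centred on its centroid; at farm scale (≤ tens of
km) the projection's distance and area distortion is far below every
tolerance used here. Transects are parallel lines along a heading
(default: the long axis of the minimum rotated rectangle, which minimises
turns), spaced `swath·(1 − sidelap/100)`, with the outermost lines at most
half a spacing from the boundary. Each transect is clipped to the polygon's
extent over the half-spacing band it images on either side — clipping at the
line's own row alone leaves uncovered wedges near polygon apexes — and
extended by a lead-in/lead-out overshoot (default half a swath) so corner
slivers stay imaged. Together these guarantee that every interior point lies
within swath/2 of a transect for any sidelap ≥ 0; the test suite checks
≥ 99 % areal coverage on randomized convex polygons at 10 % sidelap.

Mission estimates divide transect path length by ground speed and split the
result by the airframe's endurance into sorties (`ceil`, with an exact-fit
flight counting as one sortie). The feasibility report grades wind against
the 15 km/h operating limit (hard fail above it), flags waypoints beyond the
10 km radio range from a declared ground-station point, warns when the
altitude leaves the recommended 100–180 m band or when more than one sortie
is needed, fails outright on rain, and surfaces humidity, thick forest and
populated areas as advisories.

## Geo-referencing

A flight log is a strictly increasing ~10 Hz sequence of GPS fixes with
barometric altitude AGL, course and speed (CSV, or GPX when the caller
explicitly asserts the elevations are barometric AGL). An image event is
synchronised by timestamp — after applying a user-supplied camera-vs-GPS
clock offset, default 0 s since trigger latency is rig-specific — and the
aircraft state is linearly interpolated between the bracketing fixes
(circularly for course, so tracks straddling north interpolate through 0°
rather than 180°). Events outside the log span are an error; extrapolation
is never attempted.

Nadir exposures project to a ground rectangle of the footprint dimensions,
centred on the sub-aircraft point and rotated to the course over ground.
Aircraft roll and pitch are ignored: the reference rig accepted wind-induced
distortion as immaterial to detection, and the log carries no attitude.
Oblique video frames cannot be rectified without attitude, so they place a
single ground point where the optical axis meets the ground,
`h/tan(depression)` ahead along course, carrying a documented 50 m
positional uncertainty. Footprints are emitted as GeoJSON features; an
optional six-line ESRI world file georeferences each image's north-up
bounding box, with the footprint rotation preserved in the GeoJSON sidecar
rather than in the affine (raster resampling of actual pixels is out of
scope). Coverage analysis unions footprints in the local metric frame and
reports covered area and residual gap polygons against a survey polygon.

## Detection bookkeeping

Observations follow the flight-campaign schema: flight, camera
(still_photo / thermal_video / visual_video), target (rhinoceros / people /
fence), a *set* of habitats (a fence line can cross several), result, and
the minimum/maximum altitudes at which the target was confirmed (equal when
it was located once; absent when not confirmed — both enforced as
invariants). Classification rules:

* **Time period**: morning 07:00–10:15, midday 10:16–14:00, evening
  14:01–17:45, night 17:46–20:00 local time, bounds inclusive at minute
  resolution; anything else is unclassified. A flight spanning a boundary is
  binned by its start time.
* **Habitat**: forest iff vegetation cover strictly exceeds 75 % (cover of
  exactly 0.75 is grassland); farm-boundary locations are mixed regardless
  of cover, because fence maintenance trails keep them effectively open.
* **Image quality**: high when the target is identified at first glance (for
  fences, poles *and* wires resolved); medium when identification needs
  zooming, slow motion or post-processing (poles without wires); low when an
  object is detected but unidentifiable. Inconsistent evidence flags are
  rejected.
* **Confirmation**: confirmed iff at least one high- or medium-quality
  image; an empty image list is not confirmed.

Summaries group observations and report confirmed/not-confirmed counts and
the extreme confirmed altitudes. Grouping by habitat explodes multi-habitat
records (each record counts once per habitat class it touches); any other
grouping counts each record exactly once. The packaged
`table2_flights.csv` fixture carries the 20 reference flights (8
still-photo, 11 thermal, 1 HD video; 4 thermal flights at night) with a
flight_id column making the flight structure explicit.

## Survey simulator

The simulator manufactures everything the other modules consume, with a
single seeded generator per run so results are bit-reproducible:

* **Landscape**: a square extent tiled by 100 m habitat cells, with the
  forest-cell count fixed as an exact quota `round(fraction·n_cells)` —
  realized forest fraction differs from the request only by rounding.
  Fences run along the extent boundary. Geometry is anchored at a
  KwaZulu-Natal-like latitude so WGS84 outputs look like the real thing.
* **Targets**: rhinoceros at the reference density of one per 200 ha by
  default, uniform over the extent; people cluster within 300 m of the
  boundary fence (the characteristic intrusion pattern) and are labelled
  mixed habitat there.
* **Flight**: 10 Hz fixes along the serpentine plan at constant ground speed
  and altitude, optional Gaussian cross-track jitter, exposures at the
  camera frame rate, all timestamps strictly increasing.
* **Detection**: a target inside at least one footprint is detected with
  probability `base(camera) · period_factor · habitat_factor`, zero above
  the camera's maximum effective altitude; detected targets receive
  independent quality draws that run through the real confirmation rubric.
  The default factors are qualitative encodings of the field experience —
  visual cameras best morning/midday and nearly blind at night, thermal best
  morning and night, forest hiding targets — and are documented simulation
  defaults, not field estimates: no per-pass detection counts exist to fit
  them. No false positives are generated by default; a rate parameter exists
  for robustness experiments.

What the simulator does *not* emulate: animal movement, aircraft dynamics
and wind, GPS/barometric sensor noise beyond optional track jitter, terrain
relief, image content. Passing end-to-end tests therefore demonstrate the
internal consistency of the geometry, planning and bookkeeping chain — that
planned missions cover their polygons, that simulated exposures reproduce
the closed-form overlap, that detection frequencies recover configured
probabilities — not field detectability, which only flight campaigns can
measure.

## Numerical choices and limitations

* Spherical transverse Mercator (IUGG mean radius) for all local frames;
  error relative to an ellipsoidal projection is <0.1 % at these extents.
* Overlap clamps at 0 and is capped just below 100; coverage fractions use
  distance-to-transect semantics (round-cap buffers).
* Sortie counts use `ceil` with a 1e-9 relative guard so an exact
  endurance-length flight is one sortie.
* Seconds are truncated when binning clock times into the minute-resolution
  period table.
* The planner assumes a single polygon per mission, no wind-aware routing,
  no battery model, no no-fly zones; the georeferencer does no bundle
  adjustment or orthomosaicking. These are out of scope by design.

## Problem sizes in the tests

Simulation-backed tests use farm-scale problems — 100–1000 ha landscapes,
single flights of a few thousand fixes, 1000+ covered targets for the
binomial-recovery check — chosen as the smallest sizes at which the
statistical assertions (99 % binomial intervals, 1-percentage-point overlap
agreement, 99 % coverage) are meaningful.
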