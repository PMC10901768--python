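# Methods

This note documents the procedures the package implements, the defaults
it ships, and the design choices made where the underlying analysis
protocol left the operational rule open.

## Geodesy

All distances are haversine great-circle distances on a sphere of radius
6371.0 km (mean Earth radius). Ellipsoidal geodesics differ by < 0.5 %,
immaterial against the 30–50 km thresholds used throughout. Planar work
(grid binning) uses the spherical Lambert azimuthal equal-area projection
with the centre defaulting to (54°N, 8°E), near the Wadden Sea — the hub
of the flyway — and configurable per run. (Published descriptions of this
projection centre sometimes print 8°W; that longitude lies in the North
Atlantic, so the package defaults to the Wadden-Sea-consistent 8°E.)
Grid cells are half-open squares `[i·c, (i+1)·c)` anchored at the
projection origin, 300 km by default, making binning deterministic.

## Cleaning cascade

Order: class filter → duplicate fusion → burst thinning → speed gate →
median smoothing. Each stage reports removal counts to a QC table, so
`removed + retained = input` per stage.

* **Class filter** drops Argos location class Z (invalid); classes
  3…0, A, B are kept for the later stages to judge.
* **Duplicate fusion**: at a shared timestamp a GPS fix beats a Doppler
  fix; two fixes from the same system are resolved by the minimum summed
  great-circle distance to the two neighbouring (previous/next distinct
  timestamp) fixes, with a window of exactly the two adjacent fixes. At
  the track ends the single available neighbour is used. Equal costs keep
  the first-listed fix.
* **Burst thinning** scans forward and removes the *later* fix of any
  pair spaced < 10 min, iterating to a fixed point; keeping the earlier
  fix preserves bout onsets. The first fix always survives.
* **Speed gate** (default 30 m s⁻¹): a forward scan keeps a fix only if
  the speed from the last kept fix is admissible, equivalent to
  iteratively deleting the later member of the first offending pair.
  Blame is assigned to the later fix because, in a forward scan, it is
  the outlier candidate. The threshold is stored in m/s; 30 m s⁻¹ ≡
  108 km h⁻¹.
* **Median smoothing** (k = 3, odd k required): each interior fix is
  replaced by the coordinate-wise running median; the first and last
  fixes are untouched, timestamps never change. Longitudes are unwrapped
  around ±180° first so antimeridian crossings smooth continuously. The
  filter is idempotent on monotone coordinate sequences.

## Segmentation

Stationary runs are maximal sequences (≥ 2 fixes) within 30 km of the
run's incremental centroid. 30 km sits above the residual location error
of the worst usable Argos classes after median filtering and below the
50 km scale that separates distinct sites. Consecutive runs whose
centroids are ≤ 50 km apart are merged, so a sub-50 km excursion-and-
return does not split a residency and noise-induced run splits heal.

Labels:

* **Wintering** — every run within 50 km of the anchor run, which is the
  run containing the deployment fix (falling back to the longest run
  overlapping Nov–Feb). If the deployment run itself qualifies as a
  breeding candidate (an Arctic-tagged track), the Nov–Feb rule is used
  instead.
* **Breeding** — for adults, the longest run with centroid ≥ 60°N
  overlapping 15 May–15 Aug and lasting ≥ 7 d. The duration floor keeps
  a truncated track's last en-route stop from masquerading as the
  breeding residency.
* **Summering** — only when no breeding run exists (immature birds that
  stop short): the longest mid-latitude run > 30 d inside the same
  window.
* **Stopover / stationary** — every other run, split at 24 h observed
  span (> 24 h = stopover). Inter-run gaps become travelling phases; a
  track with no run reaching 24 h anywhere is classified all-travelling
  (no residency anchor to cut journeys at).

Migration events run residency-to-residency; an event is complete iff
bounded at both ends. Season is the sign of the net latitudinal
displacement (poleward = spring), ties broken by departure month.

## Timing and metrics

Sparse schedules clip stops, so arrival at a stop is back-extrapolated:
*t*(last travelling fix) + remaining distance ⁄ mean bout speed, where
bout speed is the travelling bout's path length over elapsed time
(path-based, matching "travel speed"). Departure is symmetric, using the
following bout. Estimates are clamped into the bounding-fix bracket. When
the bounding fixes straddle ≥ 24 h, no estimate is made and the dependent
durations are flagged invalid and excluded from summaries — large gaps
would otherwise dominate the error budget.

Migration duration is decimal days between (estimated) departure and
arrival; distance is the summed great-circle fix chain from the end of
the origin residency to the start of the destination residency, closed
back to the two residency centroids (run detection may absorb the first
or last in-flight fix into a residency; the closure keeps the chain
anchored at the true residence). A travelling-bouts-only distance is
available as a switch. Speed = distance ⁄ duration identically.
Incomplete events report only stopover counts and durations. Dates are
UTC day-of-year (1 Jan = 1); no local-time conversion is attempted.

## Stopover network

Visits cluster into sites by single linkage on great-circle centroid
distance, cut at 50 km — the only separation scale stated for
consecutive stops. Single linkage can, in principle, chain two centroids
to within the cut distance; on journey-scale data (stops hundreds of km
apart) this does not arise, and complete linkage is available if it
does. Site ids are ordered by earliest visit, making clustering
deterministic under input order.

Usage per site = stopping trips ⁄ crossing trips, a trip crossing when
the great-circle-interpolated path between consecutive fixes passes
within 50 km of the centroid (the corridor mirrors the site-separation
scale). Accumulation curves add birds in random order, 100 permutations
by default, reporting the mean ± sd of cumulative distinct sites — the
same quantity vegan's `specaccum(method = "random")` computes.
Grid summaries count distinct individuals per 300-km cell per season,
treating a bird tracked in two years as two individuals; region
summaries use six editable polygons (West Africa, Western Europe south
of the Wadden Sea, the Wadden Sea, North Europe, European Russia,
Siberia), first match wins with the Wadden Sea checked first.

## Regressions

Four responses — arrival date, migration speed, stopover count, total
stopover duration — are modelled per season against departure date with
wintering origin (GB vs Europe) in interaction. Families are Gaussian
except a log-link Poisson for the count. Backward selection starts from
the full model, tests the interaction first, and never drops a main
effect while its interaction survives; each removal is tested by a
deviance-based F statistic with dispersion estimated from the larger
model (for the Gaussian family this is the exact partial F of the linear
model) or a χ² likelihood-ratio test for Poisson, at α = 0.05. A
zero-deviance start (constant response) is re-seeded from the
least-squares solution. Under a pure-noise simulation the interaction
survives in ≈ α of replicates — the selection is calibrated, verified by
Monte-Carlo in the test suite.

## Synthetic journeys

The generator emulates the *structure* of the tracked journeys, not
their behavioural detail: great-circle flight legs at a fixed 60 km h⁻¹
bout speed joining parked dwells at waypoints. Defaults: origins at the
Bijagós archipelago (11.0°N 15.8°W), Tagus estuary (38.75°N 9.05°W) and
Moëze-Oléron (45.9°N 1.1°W); breeding on the Yamal peninsula (70.5°N
70°E) or European Russia; 2–6 stopovers of 1.1–20 d plus 0–2 stationary
stops of 0.2–0.8 d placed along the route with ≤ 120 km lateral scatter
and > 50 km mutual separation; departures on day-of-year 121–135;
20 d pre-departure wintering and 30 d breeding dwells.

Device models: Argos PTT (fixes within 10 h ON windows of a 35 h cycle,
mean 1.5 h spacing, class mix 3/2/1/0/A/B = .10/.15/.25/.20/.15/.15 with
2 % class Z), PinPoint GPS-Argos (3–5 GPS fixes/day, occasional Doppler
shadows and 2-min bursts), GPS-UHF (hourly). Positional error is
Gaussian per axis with class sd 0.25/0.5/1.5/5/10/20 km (conventional
CLS nominal accuracies; class Z 500 km) and 0.03 km for GPS; all
configurable, and a zero-noise variant reproduces the true path exactly.
All scatter is measurement noise — the bird is parked during dwells — so
ground-truth distances are exactly the summed leg geodesics and the
zero-noise limit is a strict oracle for the whole pipeline.

What the generator does **not** emulate: wind drift, within-stop foraging
movement, fuelling-dependent departure decisions, Argos orbital geometry
(fix density varies only through the duty cycle), and habitat-driven
site choice. Passing tests therefore demonstrate that the pipeline
recovers journey structure under realistic sampling and error regimes,
not that it would resolve behaviour the generator does not produce.

## Problem sizes and numerical choices

The shipped checks use 20-bird cohorts (the scale of the original
deployment), 500-replicate calibration runs, 100-permutation curves and
10⁴-pair geodesic audits; all complete in seconds to a couple of minutes
on one CPU. Tie-breaks are deterministic everywhere (first-listed fix on
equal fusion costs, earliest-visit site ids, month rule for season
ties); every stochastic step takes an explicit seed, and pipeline runs
are byte-identical under a fixed config + seed.

## Known limitations

* Phase boundaries are quantised to the sampling interval; duty-cycled
  tags can miss stops shorter than the OFF period entirely (the
  recovery tests tolerate ±1 stopover per journey for Argos sampling).
* The wintering/breeding/summering rules are heuristics standing in for
  what was originally an expert-supervised classification; they are
  deliberately conservative and all thresholds are exposed.
* Usage proportions depend on the corridor width; 50 km is a convention,
  not an estimate of detection probability.
* Site counts from 50-km single linkage are a property of this
  delineation rule; other rules (or other data) will give other counts.
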