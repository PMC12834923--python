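# Methods

## The study being modelled

A multi-reader multi-case crossover design: three radiologists read the
same 180 chest radiographs twice, once with concurrent CAD bounding-box
prompts and once without, separated by a washout. The display operating
point is fixed by construction (96 TP / 12 FN / 12 FN+FP / 48 TN / 12 FP,
i.e. 80 % display sensitivity and specificity). Gaze is sampled at 60 Hz;
five metrics summarise each read; the primary analysis contrasts the two
conditions on the TP cases each reader completed validly in both
sessions.

## Metric definitions and numerical choices

All metrics operate on raw gaze samples; no fixation-detection filter
(I-DT/I-VT) is applied, so "first fixation" means first valid sample
inside the area of interest.

- **Boxes** are half-open pixel rectangles `[x_min, x_max) x [y_min,
  y_max)`; AOI membership after margin expansion is inclusive of the
  boundary. Both choices make membership arithmetic exact and cheap to
  oracle.
- **Dwell** counts each valid in-AOI sample as one sampling interval
  (1/60 s). No interpolation across dropped samples: the device's
  validity flag is taken at face value, as the capture-ratio criterion
  presupposes.
- **Path length** connects consecutive *valid* samples, bridging dropout
  gaps of any length. Whether a real study bridges long gaps is not
  derivable from the metric's verbal definition; bridging is this
  package's convention and the per-read maximum bridged gap is visible in
  the raw logs.
- **Coverage** anchors the 50-px grid at the image origin. A tile belongs
  to the lung field iff its centre pixel is inside the mask (partial edge
  tiles whose centre is off-image are not tiles); a lung tile is covered
  iff its closed square lies within the 50-px buffer distance of the gaze
  polyline (`shapely.dwithin`, mathematically identical to
  buffer-and-intersect on closed sets). The tests verify this against a
  from-scratch segment-to-box-distance oracle to machine precision, and
  against a pixel-rasterisation oracle everywhere the tile's clearance
  exceeds the 1-px raster step (a discrete raster cannot resolve
  sub-pixel grazing contact, so knife-edge tiles are excluded from that
  comparison only).
- **Capture ratio** divides valid samples by `round(duration x 60)`: the
  nominal device rate defines the expectation, and the validity rule is
  strictly greater than 0.5 ("more than 50 %"), so a ratio of exactly 0.5
  is invalid.
- Times are floating-point seconds throughout; no frame-index arithmetic
  is exposed.

## The mixed model

For each metric, `y ~ condition` with independent crossed random
intercepts for case and reader, REML-estimated (statsmodels `MixedLM`
with the two factors as variance components on a trivial grouping — the
standard crossed encoding). The fixed effect is the session-1-minus-
session-2 contrast with Wald normal 95 % CI and p-value; the inference
convention is recorded in every result object. With only three readers
the reader variance often sits at the zero boundary; boundary fits are
reported as-is with a flag rather than re-specified. Reads whose gaze
never entered the AOI are dropped from the TTFF model only, and counted.
Time metrics are modelled on the natural (seconds) scale despite their
skew — the estimand is an additive shift in seconds — and the residual
diagnostics (Shapiro-Wilk, scale-location slope) duly flag the
non-normality on every simulated dataset; they are advisory and never
alter results. A 500-replicate null simulation at reduced scale (24
cases, 3 readers) puts the empirical type-I error of this procedure at
0.03-0.05 per metric.

## The synthetic-data generator

The generator's purpose is a known ground truth for every downstream
stage, not oculomotor realism. It has two layers.

**Statistical layer** (`simulate_metric_values`): each read draws latent
values of the five metrics as `median x case-factor x read-noise +
condition-shift`, where medians are the reader's no-CAD baselines
(bundled defaults: 10.2/4.4/8.6 s interpretation time, 1.2/0.4/1.3 s
dwell, 1.9/2.7/1.4 s TTFF, 5706/2308/4782 px path, 68.0/46.8/62.4 %
coverage for readers 1-3), case factors and read noise are log-normal
(per-metric sigma 0.33/0.45/0.50/0.33/0.07, applied at both levels so the
case layer realises the case random intercept), and the condition shifts
are additive on the natural scale (+4.9 s, +1.3 s, −1.3 s, +2076 px,
+10.5 points when a box is displayed) to match the additive mixed-model
estimand. Two correlations are built in: path with coverage (rho 0.75)
and TTFF with duration (rho 0.6), at both levels — wandering farther
covers more lung, and a read is long largely because the target took long
to find; without them, independent draws produce geometrically impossible
path/coverage pairs and TTFF values beyond the read duration. Floors keep
every metric in its domain (times positive, TTFF ≥ 0.05 s, coverage
clipped to [0.02, 0.98], dwell rescaled to ≤ 0.8 x duration with a flag).

**Geometric layer** (`simulate_scanpath`): a sample stream is constructed
whose *measured* metrics land on the drawn targets. The sample count
fixes the duration exactly. Dropout is drawn per read (Beta around the
reader's rate; spread is what occasionally pushes a read under the
validity threshold) and the construction is dropout-aware: the lesion
visit is scheduled so the first *valid* in-AOI sample sits at the TTFF
target and the count of valid in-AOI samples matches the dwell target,
because the metrics — like the real ones — are computed from valid
samples only. Coverage is produced by growing a compact region of lung
grid tiles and scanning it in three-row boustrophedon bands (one run per
band across its x-span, each lung routed separately), with the region
size iterated against the actual coverage metric; path length is then met
by bisecting the amplitude of a perpendicular zigzag on the valid-sample
polyline, and the two loops alternate because the zigzag also widens the
covered band. Route tiles near the lesion AOI are excluded (with sample
push-out as a safety net) so no unscheduled dwell can occur; all samples
are clipped to the frame.

**Stated construction tolerances.** Duration is exact; dwell and TTFF
land within two sampling intervals; on unflagged reads the path is within
10 % of its target and coverage within 3 grid tiles or 0.06, whichever is
larger. Reads where the targets are geometrically unreachable are
flagged (`path_overshoot`, `path_shortfall`, `coverage_unmet`,
`dwell_rescaled`, ...) in the latent-truth table rather than silently
adjusted.

**Lung masks** are two disjoint ellipses laid out like a portrait
radiograph pillarboxed fit-to-height on the 2560x1440 display: the lung
fields occupy ~15-19 % of the full frame (40-50 % of the central
square window), matching the display geometry the metrics presuppose.
This matters quantitatively: a buffered scan covering a fraction C of N
50-px tiles needs at least ~16.7·C·N px of path, so oversized lungs make
the bundled path/coverage medians jointly unreachable and would censor
the path metric.

**Decisions** are Bernoulli draws from each reader's unaided operating
point (bundled: sensitivity 67.5/79.2/60.0 %, specificity
95.0/63.3/96.7 %); in session 1 the positive-call probability is pulled
toward the display by an adoption weight (0.60/0.90/0.65), chosen to
reproduce the observed ordering of display concordance across readers.

**Determinism.** One root seed drives a `SeedSequence` tree (allocation,
per-case masks/boxes/factors, per-read streams); identical seeds give
bit-identical datasets, including the dropout pattern and decisions.

## What the generator does and does not emulate

It emulates: the crossover design and case mix, 60 Hz sampling with
realistic dropout and occasional invalid reads, reader-specific baselines
and display-adoption behaviour, metric distributions with case and reader
heterogeneity, and condition effects of the calibrated sizes. It does
not emulate saccade velocity profiles, microsaccades, blinks, pupil data,
calibration drift, anatomy-driven search habits, or any dependence of
behaviour on lesion conspicuity. Passing the pipeline's recovery tests
therefore shows that the *analysis chain* is correct and unbiased under
the stated data model — not that real gaze data would satisfy that model.

Two known attenuations of the recovered contrasts, both visible in the
latent-truth flags and both leaving the estimates inside their acceptance
bands: (i) the TTFF shift truncates at the 0.05 s floor for fast readers,
so the recovered magnitude (~1.0 s) sits below the injected 1.3 s; (ii)
for reader profiles whose baseline path medians lie at or below the
coverage feasibility frontier, realised paths are floor-limited
(`path_overshoot`), inflating path medians above their targets while the
condition *difference* stays on target. Raising the sampling rate or
loosening the coverage targets would remove (ii) but would depart from
the bundled study conditions.

## Problem sizes used by the checks

The bundled end-to-end run is the full study scale (3 readers x 2
sessions x 180 cases, ~1 minute single-core). Calibration experiments
(type-I error) use 500 replicates of a reduced 24-case design through the
statistical layer, since the geometric layer contributes nothing to the
metric values it is built to reproduce. Metric oracles run on 300x300
frames where exhaustive per-pixel and per-segment checks are affordable.
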