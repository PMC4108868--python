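# Methods

## The test and its geometry

The Halo test measures visual discrimination under glare: a
high-luminance central disc on a dark background, with faint peripheral
spots flashed one at a time along radial spokes (semiaxes). Misses
concentrate near the centre when the observer perceives a halo.

The geometry is parameterised by the central radius, peripheral radius,
maximum radius (centre-to-centre, to the farthest spot), spots per
semiaxis, and number of semiaxes. Only the endpoints of the ring
sequence are determined by those parameters; the placement of the
intermediate rings is a design choice. This package places the
innermost ring tangent to the central disc (distance = central radius +
peripheral radius), spaces the remaining rings equally out to the
maximum radius, and rounds fractional positions **up** to whole pixels.
Under the reference protocol (25 px disc, 1 px spots, 60 px maximum, 4
rings) this puts the rings at 26, 38, 49 and 60 px; ceiling rounding is
the only simple rounding rule consistent with that published layout
(37.33 → 38, 48.67 → 49).

Semiaxis 0 points rightward on screen and successive semiaxes proceed
counter-clockwise; the angular origin is not fixed by the protocol and
only relative geometry matters to the index. Screen coordinates use the
raster convention (origin top-left, y down), so a stimulus at angle a
and radius r sits at `centre + r·(cos a, −sin a)`. All distances are
centre-to-centre.

Pixel-to-degree conversion needs the monitor's pixel pitch, which is
hardware-specific; it is therefore an explicit configuration field with
no default, and `pixels_to_degrees` requires the caller to say whether
the extent is radius-like (atan(L/d)) or diameter-like (2·atan(L/2d)),
since published subtenses are quoted both ways.

## Scheduling and response matching

A session is the multiset of stimulus ids (each repeated `weight`
times) in a uniformly random order. One seeded generator drives both
the permutation and the inter-trial gaps, so a schedule is a pure
function of (layout, seed). The first onset follows the dark-adaptation
and central-stimulus-adaptation periods (180 s + 60 s by default); each
trial lasts the exposure time (1 s) and consecutive trials are
separated by a blank gap drawn uniformly from the refresh interval
(0.8–2 s). The refresh interval is interpreted as the offset-to-onset
blank during which only the central stimulus is visible — the only
reading consistent with gaps shorter than the exposure.

A click is attributed to the trial whose **response window** contains
it: from the trial's onset to the next trial's onset (for the last
trial, offset plus the maximum refresh gap). Extending the window
through the following blank reflects human reaction times, which
routinely exceed a 0.8 s gap. The first click in a window detects the
trial; surplus clicks in a window, and clicks in no window (including
during the adaptation periods or after the session end), count as false
positives. Misses are presentations minus detections, which enforces
the conservation law `Σ detections + Σ misses = N × weight` checked by
the test suite. A truncated click log is scored against the full
schedule by default — a subject who stops responding misses the
remaining trials — with an optional cut-off that drops unreached trials
instead (an aborted run).

## Scoring

`compute_vdi` implements the squared-distance-weighted miss fraction
and requires a uniform presentation count across stimuli (the weight
p); the index is exactly 0 at full detection and 1 at total miss,
strictly increasing in every miss count, and invariant under uniform
rescaling of the radii (r² cancels). An independent double-loop
implementation serves as the numerical oracle in the tests (agreement
to 1e-12).

`halo_extent` summarises the halo shape as, per semiaxis, the largest
ring radius such that every ring at or inside it has miss fraction at
least a threshold. The default threshold of 1.0 counts only complete
misses, tracing the core of the disturbance; it is exposed because the
boundary of a perceived halo is not sharply defined and softer
thresholds (e.g. 0.5) trace a wider penumbra. A missed ring beyond a
detected one is excluded — the extent describes a contiguous core, not
isolated lapses.

In rendered maps, a stimulus shows its detected count whenever it was
detected at least once (so `1` covers detected-once-missed-once at
weight 2) and `X` only when never detected. Text output prints the VDI
to two decimals, matching clinical reporting; machine-readable exports
keep full precision.

## The simulated observer

No observer model is part of the test itself; the one here is
phenomenological plumbing that makes the pipeline testable with known
ground truth. Detection probability rises with radial distance r as

    P(r) = guess + (1 − guess − lapse) · F(r)

with F logistic in r with midpoint `halo_radius_px` (the 50% threshold
radius — the proxy for perceived halo size) and steepness `slope` (per
pixel). A Weibull CDF is available as an alternative form; there
`slope` is the shape parameter and the characteristic radius marks the
~63% point. Logistic is the default as the most common choice in
detection psychophysics. `lapse_rate` (miss despite visibility) and
`guess_rate` (click despite invisibility) are bounded at 0.2, beyond
which a psychometric fit is meaningless. Defaults: halo 30 px, slope
0.25/px, lapse = guess = 0.02 — a moderately impaired observer whose
halo covers the innermost ring of the reference layout.

Detected trials emit a click at onset plus a normal reaction latency
(mean 0.45 s, SD 0.10 s — typical simple reaction times to faint
stimuli). Latencies are clipped into the trial's response window so the
simulator never generates attribution ambiguity; a `sloppy` mode leaves
them unclipped to exercise false-positive handling.

Because E[p_i] = p·(1 − P(r_i)), the expected index has the closed form
`E[VDI] = Σ (1 − P(r_i))·r_i² / Σ r_i²`, which the Monte-Carlo tests
check against simulated sessions (3 SE over 500 sessions).

Binocular viewing is modelled as probability summation of the two
monocular observers, `P_bin = 1 − (1 − P_L)(1 − P_R)`: detection needs
only one eye. This is a modelling choice, not an empirical claim; it
reproduces the classical binocular-summation advantage (binocular VDI
below monocular) qualitatively.

`recover_halo_radius` fits (halo radius, slope) by binomial maximum
likelihood over per-stimulus detection counts pooled across sessions.
Guess and lapse are held fixed at supplied values rather than
co-estimated: with only four distinct radii they are not identifiable
from realistic session counts. The optimiser is L-BFGS-B from three
starts (empirical 50% crossing and two generic points) with the halo
radius bounded in (0, 2·max radius] and slope in [1e-3, 10].
Confidence intervals are bootstrap percentile intervals over sessions
(over stimuli when only one session is given). All-detected or
all-missed data are flagged non-identifiable and return a boundary
estimate with a warning rather than a spurious fit.

## The synthetic cohort

`simulate_cohort` emulates a pre/post drinking study: by default 20
subjects, baseline halo radii Normal(30, 5) px with a small (SD 1.5 px)
inter-eye difference, breath alcohol content uniform on 0.14–0.76 mg/l
(a realistic social-drinking range), and a post-drink halo enlargement
of 20 px per mg/l of BrAC — chosen so that mean deterioration is a
clearly measurable fraction of the index while low-BrAC subjects change
little. Pupil diameters are drawn around typical mesopic values
(Normal(5.3, 0.9) mm) with a small BrAC-dependent post enlargement.
Every subject/condition/eye cell is produced by the full pipeline
(schedule → simulated clicks → matching → scoring), not by sampling
miss counts directly.

The generator reproduces the qualitative structure of a real study —
post > pre VDI, binocular < monocular, deterioration increasing with
BrAC, a larger pre/post gap in the high-BrAC cohort — by construction,
so passing the directional tests validates the pipeline's plumbing and
the index's behaviour, **not** any claim about human drinking
physiology. What the generator does not emulate: learning and fatigue
across a session, criterion shifts, reaction-time slowing with alcohol,
spatially anisotropic halos (simulated misses are radially symmetric up
to sampling noise), and any optical mechanism (glare spread, pupil
optics, MTF).

## Analysis

Analysis mirrors a pre/post paired design. Deterioration is VDI(post) −
VDI(pre), positive when discrimination worsens. Cohorts split at the
0.25 mg/l BrAC driving limit, the boundary subject going to the low
group. Paired comparisons use the classical closed-form paired t
(identical vectors return t = 0, p = 1; constant nonzero differences
are flagged degenerate with infinite t rather than erroring, since the
mean difference is still informative). The deterioration-on-BrAC fit is
ordinary least squares with r² and the slope test. p-values are raw by
default, as is conventional for this design; a flag applies Holm
correction. Where a single monocular value per subject is needed the
report uses the mean of the two eyes and also prints an eye-level
table, since treating eyes as independent samples is a contested
choice.

## Numerical and interface choices

- Ceiling rounding of ring positions uses a 1e-9 snap-to-integer guard
  so float division cannot push an exact position up a pixel.
- Validation reports **all** violated configuration invariants in one
  error, keyed by field name.
- Session-level seeds derived inside higher-level drivers are drawn
  below 2^31 so they remain portable integers.
- Degenerate inputs: a single-stimulus layout, weight 1, and empty
  click streams are all legal and exercised in the tests; an empty
  cohort or missing measure produces a warning and an omitted row, not
  a crash.
- Problem sizes in the validation suite — 500 sessions for the
  Monte-Carlo check, 50 for parameter recovery, 20 synthetic subjects
  for the directional study — were chosen so each check resolves its
  effect comfortably (3 SE margins, ±3 px) while the whole suite runs
  in well under a minute.

## Known limitations

- The observer model is phenomenological; its halo radius is a
  detection threshold, not an optical measurement, and the rendered
  miss map is a detection-failure map, not the subject's phenomenal
  halo.
- Visual-angle conversion is only as good as the supplied pixel pitch;
  none is assumed.
- The analysis module implements the classical tests of a paired
  design; it does not model repeated measures beyond pairing, nor
  between-eye correlation.
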