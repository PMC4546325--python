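# Methods

This note documents the models, parameter choices and numerical decisions
behind `myxotrack`, and what the synthetic benchmark does and does not
establish about real data.

## The measurement problem

A gliding *Myxococcus xanthus* cell is a ~5 × 0.7 µm rod moving along its
long axis at ~1–3 µm/min. Reversals — genuine, Frz-pathway-controlled
switches of direction — exchange the roles of the leading and lagging
poles, and polarity markers such as FrzS-YFP relocalize from the old to
the new leading pole within roughly one 15-s frame. Type-IV-pilus-driven
cells additionally show stick-slip motions: short (< 1 µm) back-and-forth
displacements with no polarity exchange. A trajectory-only reversal count
therefore has a false-positive class that must be removed by correlating
each candidate directional change with the polar fluorescence traces.

## Synthetic movie generator

The generator is the package's substitute for raw microscopy data and the
source of ground truth for every downstream test.

**Kinematics.** Each cell has a constant speed drawn from a normal
distribution with mean 1.7 and SD 0.8 µm/min, truncated below at
`speed_min` = 0.5 µm/min. The floor models the selection implicit in any
motility assay: a cell below 0.5 µm/min covers less than one body length
in a 10-min track and would be scored non-motile. Headings follow a random
walk with σ = 5°/frame so trajectories are not perfectly collinear.

**Events.** Per-cell reversal and stick-slip counts are Poisson with the
configured rates (defaults 0.1/min each) over the movie duration, so
frequency estimators can be checked for bias against the generating rate.
Event *times* are then placed uniformly over the observable window of the
movie (a vertex needs both neighbouring frames; a fluorescence exchange
needs a few frames to persist past the smoothing window) and no two events
on one cell are closer than `min_event_separation_s` = 60 s (4 frames).
Two events inside one refractory window are indistinguishable from a
single vertex at this time resolution, so a benchmark that demands exact
event-level scoring must generate resolvable events; the separation is a
property of the benchmark, not of the caller. A reversal flips the heading
by 180° (± heading jitter) and swaps the target fluorescence levels of the
two physical poles over `fluor_relocalization_frames` (default 1); a
stick-slip moves the cell backward and then forward by
`stickslip_excursion` (default 0.75 µm) within two frames and leaves the
fluorescence untouched.

**Confinement.** By default each cell is placed in its own 22-µm tile and
performs a genuine, recorded reversal when it approaches the tile margin.
This emulates the practice of analysing isolated, well-separated cells and
keeps 30-min tracks inside the field of view; boundary reversals are part
of the ground truth, so event scoring remains exact. For pure Poisson-rate
statistics (no boundary events) the generator is used with
`confine=False` and a large field.

**Rendering.** The transmitted channel is a bright background
(level 1000) carrying a static smooth mottle (Gaussian-filtered white
noise, σ = 40 intensity units, correlation length 3 px) on which each cell
is a dark capsule (depth 600) with a one-pixel soft edge; the fluorescence
channel is a flat background (level 100) with a Gaussian spot (σ = 0.25
µm) at each pole whose amplitude is proportional to that pole's marker
level (leading 1.0, lagging 0.3, amplitude scale 600). Stage drift shifts
cells, spots and the background mottle coherently; Gaussian read noise
(default SD 20) is added per pixel and intensities are clipped to 16 bits.
The mottle matters: real transmitted-light movies always contain static
background structure, and it is what drift correction locks onto. Without
it, registration of a scene whose only features are the moving cells is
ill-posed.

**Not modeled:** optics beyond Gaussian spots (no PSF convolution on the
capsule), cell growth and division, cell–cell contact, photobleaching,
and focus drift. Pixel size (0.1 µm/px) and camera depth are declared
defaults, as these acquisition constants vary between microscopes.

## Stabilization

Drift is estimated on the transmitted channel by phase cross-correlation
with 1/20-pixel upsampling between *consecutive* frames, accumulated into
per-frame offsets relative to frame 0, and each frame is shifted once
(bilinear interpolation, both channels together). Direct correlation of
every frame against frame 0 is exposed as `mode="first"` but is not the
default: when cells have moved far from their frame-0 positions and no
static structure dominates, the frame-0 correlation peak is spurious
(errors of hundreds of pixels were observed on synthetic scenes), whereas
consecutive frames always overlap strongly. The cost of the sequential
scheme is a slow random-walk error accumulation (≲ 0.3 px over 120 frames
on textured scenes); with integer-pixel drift it is exact. Featureless
(zero-variance) frames contribute an identity step and a warning.

## Segmentation and pole photometry

Cells are dark on a bright background, so the foreground is
`image < threshold`. The default threshold is Otsu's, with a guard: when
the Otsu split labels more than 15 % of the field as foreground — the
classic failure mode when the true foreground fraction is far below 1 %,
where Otsu bisects the background mode — the threshold falls back to
robust background statistics, median − 5 × (1.4826 · MAD). A fixed
threshold is available for full reproducibility across runs. Components
smaller than `min_area` (default 1 µm²) or touching the image border are
discarded; border contact also terminates tracking, since a clipped cell
has a biased centroid.

Centroids are intensity-weighted (weight = darkness below threshold) and
sub-pixel. The principal axis comes from the weighted second-moment
eigenvectors; cell length is the peak-to-peak extent of the component
projected on the axis (+1 px for pixel extent) — the ellipse-equivalent
axis length would overestimate a capsule by ~15 %. Poles are the on-axis
points at the extreme projections, ordered lexicographically for
determinism; persistent identity is assigned later by tracking. Components
with an axis anisotropy below 1.3 are flagged degenerate and given an
arbitrary fixed axis.

Pole fluorescence is the mean inside a 3-px disc at the pole minus the
median of a 5–7 px annulus (local background), clamped at zero. The
subtraction makes the measurement invariant to constant offsets; discs
crossing the field edge use in-field pixels only and are flagged.

## Tracking

Linking between consecutive frames is greedy mutual-nearest: candidate
pairs below the gate `max_disp` are accepted in ascending distance order.
The gate default is 4 × (speed_mean × frame_interval) ≈ 1.7 µm so that a
reversing cell is never gated out. Exact distance ties that contest one
detection drop all tied links and leave the contested detections
unmatched. Crossing cells — a track end or a detection with two candidates
inside the gate — terminate the involved tracks at the conflict frame;
together with gate violations and degenerate-geometry flags this is the
automated, logged replacement for interactive trajectory verification. No
gap closing is performed: a missed detection ends the track. Pole labels
are assigned per frame to minimize the summed distance to the previous
labeled poles, which cannot swap while a cell moves less than half a cell
length per frame; an instantaneous 180° body rotation would defeat the
rule and is a documented limitation. Tracks shorter than 10 min
(inclusive at exactly 600 s) are removed before any frequency statistics.

## Reversal calling and classification

The turn angle at frame t is the vertex angle at the cell center between
the segments to the centers at t−1 and t+1 (arc-cosine of the normalized
dot product): 180° for straight motion, 0° for a retrace. A directional
change requires an angle strictly below 90° — 90.0° exactly is not a
reversal — and both steps at least `min_step` (default 0.1 µm = 1 px).
The step gate suppresses pseudo-angles from localization jitter while
staying below the per-frame displacement (0.125 µm) of the slowest motile
cells the generator produces; a 2-px gate would censor cells slower than
0.8 µm/min. Changes within a 2-frame refractory window of a kept event
merge into it (earliest vertex kept), so one physical reversal spanning
two vertices counts once.

Both per-pole intensity traces are smoothed with a centered 3-frame moving
average (shrinking at the edges); a fluorescence switch is a sign change
of their difference whose new sign persists at least 2 frames, with zero
differences inheriting the previous sign. Directional changes and switches
of one track are then matched one-to-one, smallest frame distance first,
within a ±2-frame window: matched changes are confirmed reversals (each
switch confirms at most one change); unmatched changes are stick-slip
when fluorescence exists, otherwise "unconfirmed" (pure-motion mode for
counting without the filter). The smoothing, persistence and window
defaults are declared choices at 15-s resolution — wide enough for a
1-frame relocalization blurred by the smoother, narrow enough that a
stick-slip 4 frames from a reversal cannot steal its switch.

Per-cell frequency is the confirmed count divided by track duration,
reported in reversals per 10 min (the unit is declared in every output);
mean inter-reversal time is reported in minutes for tracks with at least
two events.

## Group statistics

Summaries are the 10/25/50/75/90 percentiles with linear interpolation
between order statistics, plus the mean, matching the boxplot convention
(box 25–75, whiskers 10–90, thick median). Two-group comparisons follow
the n-conditional rule exactly: two-sided Wilcoxon rank-sum when
min(n) < 40, two-sample Student t-test (equal variances) otherwise —
"Student" is taken literally; Welch is available behind a flag. The
Wilcoxon p-value is computed by full enumeration of the rank-sum null
when both groups have ≤ 8 observations or the pooled sample has ≤ 10
(and there are no ties), and by the tie-corrected normal approximation
otherwise. Two zero-variance groups with equal means return p = 1 by
convention, flagged. Dose-response tables sort conditions by dose, merge
duplicate labels with a warning, and report the pairwise test between
consecutive doses. P-values are raw; no multiple-testing correction is
applied, and outputs say so.

## Validation against ground truth

Tracks map to simulated cells by mean positional distance (reject above
3 µm). Confirmed calls match true reversal frames one-to-one, closest
first, within ±1 frame (configurable); precision = matched/called,
recall = matched/true, where the truth denominator counts reversals
observable inside a matched track's frame span (a vertex needs both
neighbours). Zero calls report precision 1.0 with an explicit flag.
Tracking identity accuracy is the fraction of matched tracks whose
assigned cell is the nearest true cell at every frame.

## Problem sizes and determinism

The shipped benchmark uses 20 rendered cells × 30 min (121 frames at
15 s, ~0.9 Mpx fields) for event recovery and the imaging chain, 100
trajectory-only cells × 30 min for rate recovery, and 100 random frames
for the linking oracle; these sizes give ~150–300 events per run, enough
that exact precision/recall and 2-standard-error rate checks are
meaningful. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; a fixed seed makes simulate → render →
analyze → summarize byte-reproducible, which the test suite asserts on
the emitted CSV/JSON files.

## What passing tests do and do not show

The synthetic benchmark establishes that the chain is internally correct:
exact event recovery at zero noise, unbiased frequency estimation,
sub-half-pixel drift recovery, linking optimality on well-separated
scenes, and exact statistical rules. It does not certify performance on
real movies, where segmentation faces uneven illumination and contact
between cells, fluorescence is photobleached and stochastic, reversals
can pause rather than retrace cleanly, and relocalization kinetics vary.
The noise-ladder test (precision non-increasing with added noise) probes
robustness qualitatively, not quantitatively.
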