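# Methods

This note documents the models, conventions and numerical choices behind
`macromigr`, in the spirit of a methods appendix: what each quantity means,
which knobs matter, and what the synthetic-data validation does and does
not demonstrate.

## Coordinate and calibration conventions

Images are indexed (row, column) with origin top-left; track coordinates
are reported as x = column, y = row, sub-pixel, frames 0-based. A
`Calibration` carries µm/pixel and minutes/frame; the default frame
interval is 10 min, matching overnight (≥ 16 h) acquisitions of
tracker-dye-labeled cells. All tracking thresholds are interpreted in
calibrated units; with the default 1 µm/px calibration they coincide
numerically with pixel units, which keeps the literal defaults (70.0, 2.00,
8.00) meaningful under either reading.

## Synthetic-data generator (`simkit`)

**Motility model.** Each condition is a fixed-mode persistent random walk:
per frame the heading gains a Gaussian increment of sd `angular_sd` (rad)
and the cell advances `mean_step_speed × minutes_per_frame` µm. This is the
simplest model that separates speed from directional persistence, which is
exactly the contrast the metrics must resolve. Mode switching within a cell
is not modeled. Positions reflect at the field boundary (the alternative —
letting cells exit — would truncate ground-truth tracks).

**Slingshot events.** Events arrive as a Bernoulli process on frame
intervals with per-interval probability `slingshot_rate × Δt` (rate in
events/cell/hour). A refractory spacing (ramp length + 1 frames) prevents
overlapping events; the draw probability is inflated to
p/(1 − p·deadtime), and the refractory state is initialised from its
stationary distribution, so the realised event rate is unbiased for the
requested rate even in short windows. During an event the circularity ramps
down linearly over ⌈Δc/0.2⌉ frames (each step ≤ 0.2, safely below the 0.4
detection threshold) and snaps back by `slingshot_delta_c` in a single
frame while the cell body advances `slingshot_step` µm. Each injected event
therefore produces exactly one single-frame shape change ≥ Δc — the
elongate-then-recoil asymmetry seen in laminin slingshots, where the
elongation is gradual and only the recoil is abrupt. Circularity otherwise
fluctuates about `circ_baseline` with sd `circ_noise_sd`, clipped to (0, 1].

**Presets.** `FN_LIKE` (0.3 µm/min, angular sd 0.35, circularity 0.45, no
slingshots) and `LAM_LIKE` (0.9 µm/min, angular sd 1.2, circularity 0.8,
0.6 slingshots/h of 15 µm and Δc 0.5) are package defaults chosen to
reproduce the qualitative substrate orderings (laminin faster, less
persistent, rounder, more shape change); no measured speed or persistence
magnitudes were available to anchor them, so the numbers themselves carry
no biological meaning.

**Rendering.** Cells are drawn as elliptical Gaussian spots (base sigma
2.5 px) whose axis ratio follows the frame's elongation at constant
integrated intensity (50,000 counts), on a background of 100 ± 10 counts,
16-bit. Per-frame dropout omits cells independently to exercise gap
closing. What the renderer does **not** emulate: cell texture, cell–cell
contact and occlusion, photobleaching, uneven illumination, or focus
drift. Passing the round-trip tests therefore shows the tracker is correct
on well-formed point-like signals, not that it is robust to every
real-microscopy artifact.

**Z-stacks and adhesion fields.** The z-stack simulator puts
`ventral_fraction` of the total intensity in slice 0 and splits the rest
evenly, rendering each slice as a fixed-width Gaussian spot (so masked
fractions are exactly preserved) plus background and noise. The adhesion
simulator removes each pre-wash cell independently with `detach_prob`, so
the post/pre ratio estimates 1 − detach_prob without bias.

## Detection and linking (`trackio`)

Detection flattens the background by subtracting a large-scale Gaussian
blur (sigma = 4 × spot diameter) — same intent as an FFT bandpass
pre-filter, simpler to test — then computes the scale-normalised negative
LoG response at sigma = diameter/(2√2) and keeps local maxima above
`quality_threshold` (default 50; rendered spots respond at several hundred,
background noise below ~10). Sub-pixel refinement is a separable quadratic
fit on the 3×3 response neighbourhood, accurate to ~0.1 px on rendered
spots.

Linking follows the two-pass LAP scheme: consecutive-frame assignment
minimising summed squared distances with links beyond `max_link_distance`
forbidden (inclusive bound, so exactly 70.0 links), then gap closing
between segment ends and later starts within the same distance and at most
`max_gap_frames` missing frames. The no-link alternative is priced at
(max_link_distance)²; the slack block of the augmented matrix is free, so
the optimised objective is Σd² + d_max²·(#unmatched), which small-case
exhaustive enumeration reproduces exactly. Assignments are solved with a
Jonker–Volgenant solver on deterministically ordered inputs; equal-cost
solutions therefore resolve reproducibly, though not by an explicit
lexicographic rule. Unlinked single detections are kept as one-point
tracks so that "how many tracks" questions have unambiguous answers; the
duration filter removes them from any analysis.

Track filters are inclusive conjunctions: duration (frames spanned,
first to last) ≥ 20, mean speed (path length / elapsed frame intervals)
≥ 2.00, net displacement ≥ 8.00. Gap segments contribute their end-to-end
distance to path length.

## Motility metrics (`motility`)

Velocity is path length divided by elapsed time (µm/min). Persistence is
the directness ratio d/T — net displacement over path length — rather than
displacement per time, because it is the dimensionless statistic reported
alongside a separate velocity panel; the displacement-rate variant is
available via `track_persistence(..., method="displacement_rate")`. A
zero-length path leaves persistence undefined and is reported as missing,
never as 0. Elapsed time always spans first to last frame, including
closed gaps.

## Shape analysis (`morpho`)

Circularity uses 4πA/P² with area and perimeter measured on the same
smoothed sub-pixel contour: the marching-squares mid-crack polygon of the
binary mask, smoothed by a 5-point circular moving average. The raw
mid-crack polygon overestimates perimeters of smooth digital shapes (a
radius-30 disk scores 0.906); the smoothed contour scores it 0.994 and is
rotation-invariant to within ~1%. Cornered shapes are slightly biased up
(a digitised square scores ≈ 0.82 vs the analytic π/4 ≈ 0.785) — the
analytic value is available through `circularity_from_area_perimeter` when
exact area/perimeter are known. Results are clipped at 1.0, since
digitisation can push the raw formula above 1 on small masks.

Elongation is the major/minor axis ratio of the second-moment ellipse.
This is a stand-in for proprietary "elongation" outputs of commercial
software whose formula is undocumented; values are internally consistent
but not comparable to arbitrary-unit scales from such tools.

Shape dynamics use s_n = |C_n − C_{n+1}| over a configurable analysis
window, default the first 31 frames (5 h at 10 min/frame); the window start
is configurable because only within-experiment consistency is required.
Slingshot detection counts s_n ≥ θ with θ = 0.4 inclusive, on absolute
changes. Events per cell pools all counts in a population and divides by
the number of cells.

`trace_masks` replaces interactive wand-tool tracing with a deterministic
equivalent: threshold the frame, then let each tracked centroid claim its
watershed basin of inverted intensity. Touching cells split along the
intensity valley; a seed falling on background is an error, not an empty
mask. This automates what was a manual step, at the cost of requiring a
sensible global threshold.

## Intensity quantification (`quant`)

Ventral fraction integrates in-mask intensity per slice after subtracting
the per-slice median of a 3-px image border (assumed cell-free) and
clipping negatives; f = I₀/ΣI_z, invariant to global intensity scaling.
Masked (not whole-frame) integration is used, matching hand-outlined
per-slice measurement. Densitometry is the sum over identically sized
boxes, target/control. Intensity statistics use raw pixel values —
display-range settings never affect measurement — and log a warning when
the in-mask maximum saturates the dtype. The adhesion ratio is not clipped
at 1; counting noise can exceed it and is logged instead of hidden.

## Statistics (`report`)

Superplot summaries report mean ± SEM (sd/√n, ddof = 1) per experimental
run and the grand mean of run means per condition — deliberately not the
pooled mean, so unequal run sizes do not silently reweight experiments.
Hypothesis tests run on pooled per-cell values, matching per-cell/track n
reporting; this pseudo-replicates across runs, which is why the run-level
summary is always produced alongside.

Kruskal–Wallis, Mann–Whitney (asymptotic, tie-corrected, so identical
groups give p ≈ 1), Welch's t and one-way ANOVA are delegated to scipy.
Dunn's post-hoc is computed in-package (no maintained dependency provides
it here): pairwise z on pooled mid-ranks with tie correction, two-sided
normal p-values, Holm-adjusted by default (the adjustment is configurable
and recorded in output). Null simulations at n = 50/group put every
design's type-I rate within [0.03, 0.07] at α = 0.05.

## Problem sizes used in validation

The shipped tests and the acceptance script use 50-cell/97-frame rendered
movies (one full overnight acquisition at 10-min intervals), 100–1000-track
populations for metric and filter validation, 200 replicates for estimator
bias, and 1000 replicates for type-I calibration — sizes at which
Monte-Carlo error is well below the tolerances being asserted while the
whole suite runs in well under a minute.

## Known limitations

- Fixed-mode walks: cells never switch between FN-like and LAM-like
  behaviour within a track.
- The renderer's idealised spots mean tracking robustness to clutter,
  contact and texture is untested.
- Circularity is biased high on sharply cornered masks (see above).
- No split/merge handling in linking; colliding cells may swap identity if
  they approach within the step scale.
- Statistical tests treat cells as independent; run effects are summarised
  but not modelled (no mixed models).
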