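# Methods

This note documents the models and procedures implemented in
`junctionscope`, their assumptions, the defaults that matter, and what
the synthetic validation does and does not establish.

## Coordinate and region conventions

Coordinates are micrometers with x along the mediolateral (ML) axis
(overridable); pixel (i, j) has its center at ((j+0.5)·px, (i+0.5)·px)
with px = 0.3 µm by default (typical 40× confocal sampling). Analysis
regions are half-open boxes [origin, origin+size): an object exactly on
the far edge belongs to the next region. Every output table records
these conventions.

## Junction-graph extraction

A label image (integer cell labels ≥ 1; 0 reserved for
"outside the tissue" in movies) is scanned at pixel corners: a 2×2
window with ≥3 distinct nonzero labels is a vertex hit; 8-connected hits
cluster into one vertex whose order is the number of distinct labels in
a disk (default radius 0.5 µm — the field has no standard pixel rule
for junction order, so the radius is exposed). Corners with exactly two
labels form the bicellular boundaries; per label pair they are ordered
along the principal axis (exact breadth-first walk when the chain is
bent or split), giving edge polylines, arc lengths and end-to-end chord
angles folded into [0°, 90°]. Chains terminating on the image edge
attach to the border rather than to a nearby vertex.

Angle bins are closed, matching the inclusive ranges used in practice:
ML = [0°, 15°], AP = [75°, 90°]; intermediate edges belong to neither
bin.

**Topological self-check.** The Euler relation V − E + F = 2 (outer
face included) is evaluated on the pixel-resolution boundary complex of
the label partition — branch corners, boundary arcs, cells — where it
holds exactly on every generated tiling. Rasterized tilings are first
made proper planar partitions: checkerboard point contacts are resolved
and each label forced 4-connected. The clustered vertex/edge tables are
a sub-pixel-simplified view of the same complex and can differ from it
by occasional one-pixel attachment ambiguities, which is why the
invariant is checked on the complex itself.

## Intensity statistics

*Background* is the mean of per-ROI means over circular cytoplasmic
ROIs (radius 0.5 µm, n clamped to 20–40), auto-placed at each sampled
cell's distance-transform maximum — the reproducible analogue of
hand-drawn cytoplasmic regions.

*Edge means* are taken over pixels within half a line width (default
0.9 µm ≈ 3 px) of the polyline, restricted to the junctional skeleton,
excluding a 1 µm zone around vertices so vertex enrichment does not
contaminate bicellular measurements. *Planar polarity* averages
per-edge means within the ML and AP bins and takes the
background-subtracted ratio; an empty bin is an error, not a NaN.
*TCJ enrichment* is (disk mean − bg)/mean(incident edge means − bg) at
order-3 vertices (disk radius 0.5 µm; both radii exposed). On
noise-free renders these estimators invert the generator exactly, which
the test suite asserts to 1e−9.

*Line profiles* sample bilinearly, subtract background, and normalize
to the per-line maximum (flagged and left unnormalized when flat).
*Cohort aggregation* is strictly hierarchical — region → embryo →
cohort — so each embryo contributes one value; dispersion is SEM or SD
as selected.

## Gap analysis

A junction is scored gapped when the dimmest skeleton pixel among those
owned by the probed vertex (nearer to it than to any other vertex)
within the 0.5 µm seed disk falls below `threshold_fraction` (default
0.3) of the field's median background-subtracted junctional intensity.
The dimmest-pixel rule is what makes sub-pixel gaps (radius down to
0.2 µm) detectable; the threshold is a reproducible stand-in for subjective by-eye
scoring and is recorded in every output. The gap radius is the farthest
below-threshold skeleton pixel before the first clean 1-px annulus.

Overlapping circular ROIs merge into the minimum circle enclosing all
of them (exact for pairs; Welzl on 128 sampled boundary points
otherwise, error < 0.1 %), iterated to a fixed point so merging is
idempotent and input-order-invariant. Stratified frequency follows the
counting convention of the field: number of (merged) gaps of each order
class divided by the census of that class; a merged cluster carries its
highest-order constituent's class. Per-region counts exclude
bicellular-class gaps by default. AJ–TJ association assigns each TJ gap
to the AJ circle containing its center (nearest on ties); AJ gaps
without a partner score a TJ area of exactly 0, and a TJ gap inside no
AJ circle is reported as an anomaly and not associated (strictly,
only a TJ gap at a defective AJ site corresponds to it).

## Recoil kinetics

Traces start at the immediately-pre-ablation distance (t = 0) and are
sampled every dt = 2 s up to 8 s. Instantaneous velocity is the
frame-to-frame difference quotient, including the pre-frame interval
(whether the original measurements used pre-frame or frame-to-frame
differences is ambiguous; frame-to-frame including the pre-frame is
implemented). For a noiseless Kelvin–Voigt trace the peak equals the
first-interval velocity and underestimates v₀ = A/τ by
τ(1 − e^(−dt/τ))/dt, asserted in closed form. Traces with no
measurable recoil (peak ≤ 0 by default; optionally ≤ 2× the
pre-frame velocity SD) are flagged for discard. Group comparison uses
Welch's unequal-variance t-test via scipy. The exponential fit is a
denoised tension proxy for recovery testing; its failure is flagged,
never fatal, and the peak velocity is always reported.

## Time-lapse scoring

Per-frame junction graphs drive all trackers; the junction-positive
criterion reuses the gap threshold (background-subtracted signal above
0.3× the frame's median junctional level).

*Rosettes* (order ≥ 5) are linked across frames by nearest neighbor
(max step 2 µm/frame — ample at 6-min sampling of slowly moving
tissue, ties to the lower track id); a candidate within 1.2 µm of an
open track never spawns a duplicate, and a track must read as a compact
5-cell point (order ≥ 5 within a tight 0.4 µm disk) in at least 30 % of
its frames — two merely close lower-order vertices drifting under the
standard order disk rarely do, while a true rosette center does. Formation is "preexisting" when
present at frame 0, "rearrangement" when some pair of constituent cells
was not yet adjacent at movie start. Gap fates are exhaustive and
mutually exclusive: `no_gap`; `repaired` (gap absent for ≥2 consecutive
frames through the end); `expanding` (radius rising ≥0.1 µm on ≥2
consecutive steps); else `persistent`.

*Divisions* are scored from the furrow-onset frame t₀ supplied by the
event table (the generator's truth, or any detector of figure-8 label
shapes): the daughters are the new labels occupying the parent
footprint at t₀+1; the division completes at the first frame the
daughter interface is junction-positive and is censored — counted as a
failure to form a new interface — when that does not happen within
90 min. A neighbor-contact gap requires ≥2 consecutive low frames that
are not restored by the end of the 90-min window. Only divisions
beginning in the first 90 min are generated and scored. The cumulative
completion curve uses completed divisions as its default denominator.

*Area trajectories* average per-cell area ratios of label-tracked cells
(exact under uniform constriction); cells lost to division or field
exit are excluded pairwise, and the result is flagged unreliable below
50 % retention.

## The synthetic epithelium

The generator is the package's validation instrument. Cell meshes are
Lloyd-relaxed Voronoi tilings (3 iterations) clipped to the field;
higher-order vertices are built by contracting short internal edges
(one edge → a 4-cell vertex; a two-edge path → a 5-cell vertex, the
simplest topology-correct construction). Junctional channels draw
boundary pixels ~2 px wide at background + base intensity, scaled by
the polarity factor on ML-bin edges, with 0.5 µm vertex disks at the
configured TCJ enrichment over the mean of their incident edges, plus
seeded additive Gaussian noise (no PSF blur by default; a blur sigma is
exposed). These rules are exactly invertible by the analysis, which
pins estimator correctness before any noise is added.

Gap injection is Bernoulli per vertex with order-specific
probabilities; radii are truncated-normal (mean 0.6, SD 0.2, min
0.2 µm), and at least one pixel is always voided so sub-pixel truth
gaps exist in the image. TJ gaps occur only at AJ gap sites, with
conditional probability and half the AJ radius (TJ defects are
reported as smaller than their AJ counterparts but without numbers, so
the scale factor is a design choice).

Movies add uniform constriction (coordinates scale about the field
center, area following linear interpolation between checkpoints),
scheduled divisions (polygon split across the short axis, rotated away
from existing vertices; interface signal drawn after an exponential
delay, or never, with the configured failure probability;
neighbor-contact suppression with the configured probability) and
scheduled rosette contractions with scripted gap fates (repaired: 3
frames; persistent: constant 0.7 µm; expanding: +0.25 µm/frame).
Base meshes for movies are re-seeded until frame 0 holds no accidental
5+ vertex, so the rosette truth is complete.

### Preset calibration

Presets encode the study conditions of the cohorts they emulate. The
static mesh composition (118 cells, 28 contracted 4-cell and 9
contracted 5-cell vertices per 60×60 µm field) was calibrated once so a
50×50 µm region carries ≈94 / 24 / 8 junctions of order 3 / 4 / 5+ —
inside the reported census ranges — which makes the late-stage mutant
preset's printed per-order gap probabilities (18 % / 49 % / 78 %) imply
≈35 expected gaps per region, so the per-order and per-region
statistics are mutually consistent. The early presets print no
per-order probabilities; theirs are the late profile scaled to the
12 (mutant) and 4 (control) gaps-per-region targets. Under a shared
census the control-late per-order probabilities imply ≈11 gaps/region
rather than the 18 reported for a different marker cohort; the
probabilities are taken as authoritative for that preset and the count
is retained as metadata. Movie presets carry the published division
failure (49 % / 1 %), neighbor-gap (73 % / 8 %) and rosette-gap
(71 % / 11 %) probabilities, fate splits conditional on a gap, a
division rate of 0.02 events/cell/h (≈10 divisions per 100×100 µm
region in 90 min), ten rosettes per movie, and constriction checkpoints
of 17 % at 1.5 h and 22 % at 3 h. Absolute intensities are nominal
(base 100, background 50, noise SD 5 a.u.): the source reports no
absolute intensities or SNR, and all are exposed in the config.

## Problem sizes used in validation

The acceptance computations pool 130×130 µm fields until every order
class holds ≥2000 junctions (and ≥50 independent 50×50 µm count
regions), accumulate mutant movies until ≥450 scored divisions (which
also yields several hundred rosettes), and average five control movies
for the constriction checkpoints. At these sizes the binomial noise of
the generator itself is well below the reported effects.

## What passing tests do and do not show

Recovery tests demonstrate that the estimators invert the generative
model they were designed against — polygonal geometry, flat
backgrounds, additive Gaussian noise, circular gaps, uniform
constriction. Real tissue adds segmentation errors, uneven
illumination, photobleaching, out-of-plane signal and non-circular
defects, none of which the generator emulates; thresholds validated
here (notably `threshold_fraction` and the order-disk radius) should be
re-examined against manual scoring before quantitative use on new
imaging data.

## Known limitations

Vertex orders are measured on a fixed disk and can misread very close
vertex pairs; mechanically realistic dynamics (T1 cataloguing beyond
rosette formation, curvature, 3D geometry) are out of scope; TIFF
metadata handling is limited to pixel size; kymograph processing for
ablation is not included (vertex distances are an input table).
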