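# Methods

This note documents the models, conventions and numerical choices behind
`spindlequant`, in the spirit of a methods supplement: what each procedure
assumes, which tunables matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Coordinate and angle conventions

Stacks are `(z, y, x)` with 0-based, half-open voxel indexing; the voxel
at index *i* is centred at `(i + 0.5) · spacing`.  *y* increases from the
apical (ventricular) surface toward the pial side; physical units are
micrometres throughout.  The default voxel spacing is 0.75 × 0.09 ×
0.09 µm (z, y, x), the sampling of high-resolution confocal stacks used
for microtubule analysis; tissue scenes use 0.5 µm pixels.

The plate angle is the signed deviation of the plate's main axis from the
local apico-basal axis, i.e. the inward normal of the nearest
apical-surface segment: 0° is "vertical" (the canonical metaphase
orientation of an apical progenitor), ±90° is parallel to the surface.
The sign is positive for a clockwise tilt viewed in the coronal plane
with the apical side up and *x* to the right; the choice of which tilt
direction is positive is arbitrary (deviations are symmetric) but applied
consistently by the measurement and the generator.

## Plate orientation

The plate mask is the largest connected component above an Otsu threshold
of the (lightly presmoothed, σ = 1 px in-plane) DNA channel.  The main
axis is the principal axis of the second-order central moments of the
mask's z-maximum projection: orientation is a coronal-plane measurement,
and the projection makes it robust to which optical sections the plate
spans.  A face-on plate (Side view) has no meaningful coronal main axis;
the pipeline reports the angle only for Front-view cells and refuses
isotropic masks.

The per-cell summary statistic is the *maximal amplitude of deviations*:
max − min of the signed angle over the samples labeled metaphase through
anaphase onset.  Prometaphase samples are excluded — the window targets
spindle-orientation dynamics, not spindle assembly.  Track categories bin
every sample into six 15°-wide (outermost: open-ended) ranges; the track's
category is the plurality bin, ties broken toward the bin containing the
window median.  Bin edges belong to the bin closer to 0°, and 0° itself is
assigned to the positive-side (green) bin; this edge ownership is a
package convention, fixed and tested.

## Astral census

The region partition is anchored on the peri/centromeric heterochromatin
foci: the apical region runs from the ventricular surface to the plane
just before the apical-most focus, the basal region from just after the
basal-most focus to the basal end of the soma, and the central region —
which owns both bounding planes, being defined to contain all foci — lies
between.  Foci are local DNA maxima inside the plate mask with prominence
≥ 30 intensity units over the plate median, detected on a smoothed image
and refined to the raw-image argmax in a ±2 px (±1 section)
neighbourhood, because smoothing biases peaks sitting on the plate-rim
intensity gradient.

Astral detection operates on the coronal (z-maximum) projection of the
tubulin channel, after per-section smoothing (σ = 1 px).  A
central-spindle exclusion mask — the convex hull of the plate footprint
and the two poles, plus 2 µm pole discs, dilated 4 px for blur tails —
removes everything that is not a resolvable astral rod.  Each remaining
connected component above a baseline-aware threshold (median + 3% of the
dynamic range; the median absorbs the noise pedestal that max-projection
creates) contributes one segment whose far endpoint is the pixel farthest
from the exclusion mask.  A segment reaches the cortex when that endpoint
lies within δ_cortex of the soma boundary (Euclidean distance transform);
δ_cortex defaults to 1.0 µm and is configurable, as the underlying
"reaching the periphery" criterion is qualitative.  Endpoints exactly on a
partition plane are central (plane-ownership rule).

Views: a spindle is Front when the pole–pole axis makes < 45° with the
sectioning plane *and* spans ≤ 3 sections, else Side; an axis at exactly
45° is Side.  Central astrals are reported only from Side views — in
Front views they run along the optical axis where the projection cannot
resolve them against the central spindle, which is precisely why the
underlying counting protocol restricts central counts to Side views.  The
Front-view central under-count is therefore a property of the viewing
geometry, shared by the automated and the manual procedure.

Basal progenitors lack a reference surface contact, so their astrals are
binned by endpoint direction from the soma centroid: apically oriented
within ±45° of the ventricle direction, basally oriented within ±45° of
the pial direction, centrally oriented otherwise.  The 45° half-angle
makes the apical and basal sectors cover equal angular ranges; it is a
package default, configurable.

## Cortical profile

One central optical section per cell.  The soma contour is a one-pixel,
8-connected Moore boundary trace, oriented clockwise (coronal view,
apical up) and started at the boundary point nearest the apical-domain
midpoint.  The diffuse cytoplasmic background is the *median* intensity
of the soma interior eroded by the expected cortical-band width (3 px
default): the median is robust to the bright cortical band and to the
spindle.  Corrected values are clipped at zero (intensities are
non-negative by contract) and resampled by linear interpolation at 100
equidistant normalized arc positions s = 0.005, 0.015, …, 0.995, making
profiles of differently sized cells comparable position by position.

Region windows on the 100-point profile default to apical s ∈ [0.9, 1) ∪
[0, 0.1), basal s ∈ [0.4, 0.6), central the two flanks (reported
separately and pooled).  The fractions are a package default — the
regional boundaries of this assay are drawn graphically in practice, not
standardized — and the output metadata records that provenance.

Accuracy: with values sampled on a pixel chain of ~400–500 points, linear
interpolation reconstructs a smooth profile to ~10⁻³ absolute error for
order-unity profile values (the error scales linearly with profile
amplitude; diagonal chain steps contribute a factor ~2 over the uniform
bound).  The recovery tests therefore use order-unity generative
profiles; brighter profiles recover with the same *relative* accuracy.

## Spindle metrics

The main spindle region is the soma clipped to the y-band between the
extreme foci (band inclusive of both planes), extended by r_pole = 1.5 µm
discs around the two centrosomes, and always intersected with the soma.
Area is pixel count × pixel area averaged over the two sections
straddling the mask's z-centroid ("the two central-most sections").
Normalized mean intensity is mean(region)/mean(image); the texture metric
is the *population* SD (divisor N) of region voxels over the region mean
— the SD flavour is unspecified in common practice, so it is fixed and
documented here.  Both are dimensionless ratios, invariant to global
intensity scaling.  The soma diameter at the spindle plane is the chord
of the soma mask along the pole–pole line, marched at quarter-voxel
steps.

## Division symmetry

2D coronal-plane geometry.  The cleavage line (point + direction;
perpendicular to the anaphase separation axis, and practically identical
to the plate angle at anaphase onset) is intersected with the
apical-surface polyline; the division bisects the apical domain if the
intersection falls strictly inside the domain's arc-length interval, else
it bypasses.  An intersection exactly on a domain endpoint is a bypass:
bisection requires splitting the domain into two non-empty parts.  The
Monte-Carlo assay draws cleavage angles from a centred normal
distribution over a flat surface with a centred 1.5 µm apical domain;
cleavages too oblique to reach the annotated surface stretch count as
bypass (they certainly miss the domain).

## Tissue censuses

Zones are half-open bands toward basal (`[lower, upper)`), so a nucleus
exactly on the VZ/SVZ boundary is SVZ; nuclei are classified by centroid.
Surfaces are polyline arc lengths in µm, not pixel counts.  Rates share
one normalizer per family — VZ and SVZ mitosis rates are both per 100 µm
of *apical* surface, so VZ + SVZ = all holds exactly.

## The synthetic generator

The generator emulates the geometric and statistical structure the
measurements assume; photon-level realism is *not* claimed (no spectral
bleed-through, no photobleaching, no depth-dependent aberration, Gaussian
PSF only).  Passing recovery tests therefore demonstrates correctness of
the measurement geometry and logic, not performance on real microscope
noise or on structures an expert would find ambiguous — notably, astral
counting in real data was a manual, expert task, and agreement with human
raters cannot be established from synthetic data.

One mitotic cell: an ellipsoidal soma (default semi-axes 2.9 × 5.4 ×
5.0 µm — a ~11 µm progenitor soma) touching the apical surface; a plate
disc (radius 2.6 µm, half-thickness 0.45 µm) perpendicular to the
pole–pole axis; 8 foci by default, rendered as σ = 0.18 µm Gaussian spots
whose amplitude equals the plate level, so focus peaks are twice the
plate intensity and "brightest points in the DNA" holds by construction;
foci snap to voxel centres and keep ≥ 0.7 µm mutual distance (0.55 µm
when collinear in the central section) so each punctum is individually
resolvable — they model distinct heterochromatin puncta, not a continuum.
The first two foci sit at ±0.92 plate radii so the partition band has a
reproducible extent.  Spindle: a double cone between the poles (max
radius 0.85 of the plate radius, hence strictly inside the foci band);
astral rods are single-voxel polylines deposited into their two nearest
z-sections (a rod crossing a section boundary then stays seamless in the
coronal projection), then blurred with the PSF (default σ = 0.09 µm).
Pole spots are added after the blur so the poles remain the global
tubulin maxima by construction.  Cortex-reaching rods stop 0.35 µm inside
the boundary (well inside δ_cortex); non-reaching rods stop at 70% of the
pole–cortex distance and at least 1.4 µm short of the boundary.  Rod
placement enforces ≥ 10° boundary-angle separation, a minimum 3 µm
projected length, no crossing of the plate envelope, and ≥ 0.4 µm
clearance between the visible projected parts of any two rods — the
generator only renders configurations whose rods are resolvable
structures, mirroring the fact that countable astrals are resolvable by
definition.  Greedy placement uses farthest-point packing with restarts;
genuinely infeasible requests (too many rods at extreme tilt) raise a
geometry error rather than degrade silently.

The cortical-marker channel is uniform cytoplasm plus a one-pixel
cortical band on the central section whose values are the profile
function evaluated at the boundary chain's normalized arc position; no
PSF is applied to this channel by default.  This makes the profile
recovery bound meaningful: it measures contour-tracing and resampling
fidelity, not optical blur.  Noise, when enabled, is Poisson (given a
gain) followed by additive Gaussian; both are off in the default
fixtures.

Determinism: one `numpy` Generator per call, seeded by the single integer
argument; identical spec + seed gives voxel-identical stacks.

### Trajectory (guy-rope) model

No quantitative model of anchor-count-dependent spindle stiffness exists
to adopt, so the simplest process reproducing "fewer anchors → larger
deviations" is used: an Ornstein–Uhlenbeck angle,
dθ = −k·(n_polar + ε·n_central)·θ·dt + σ·dW, θ(0) = 0, integrated with
the exact discrete transition (stable for any k·dt).  Central astrals
contribute a small fraction ε = 0.1 of polar stiffness — they are held to
serve bipolar spindle formation rather than orientation anchoring.
Defaults: k = 0.05 per anchor per min, σ = 6 deg·min^−1/2, dt = 3 min
(the live-imaging frame interval), duration 30 min; with these, ~12
polar anchors give a mean amplitude of ~16° and ~3 anchors ~25°,
matching the observed order of magnitude for proliferating progenitors
while keeping the model explicitly phenomenological: only the
monotonicity (more anchors → smaller amplitude) is asserted, never the
absolute amplitudes.  Samples are labeled metaphase with the final sample
anaphase onset at t = 0.

### Tissue scenes

Rectangular sections (default 200 × 120 µm; VZ/SVZ boundary at 60 µm,
SVZ/CP at 90 µm) with non-overlapping 2.6 µm nuclei.  Marker rates for
the two culture conditions are the condition presets: control VZ is 62.5%
Pax6+ Tbr2− and 34.3% Tbr2+ with 58.8% Tis21+; the perturbed condition
shifts these to 53.8% / 43.1% / 68.2% and doubles SVZ mitoses; apoptosis
rates are 1.49 vs 1.59 cells per 10,000 µm².  Mitotic densities
(6 per 100 µm apical in the VZ, 1.5–3 in the SVZ) and the neuron density
(40–55 per 100 µm pial) are chosen as plausible magnitudes for
mid-neurogenesis dorsolateral cortex where no printed value pins them
down.  Ground truth records the *realized* counts, so census recovery is
exact by construction, not in expectation.

## Problem sizes and tolerances

Recovery batches use 25 Front-view plus 25 Side-view cells (200 × 200 ×
9 voxels each) — large enough that every code path (tilt range ±25°, 4–20
astrals per cell, randomized soma axes and profiles) is exercised while a
full suite run stays in the tens of seconds.  Monotonicity sweeps use 300
trajectory replicates per anchor level and 2000 simulated divisions per
spread level; the Kruskal–Wallis null calibration uses 2000 simulations
of three n = 20 groups, judged against the binomial 95% interval around
α = 0.05.  The permutation oracle for the omnibus p uses 10⁵ label
permutations on a fixed 3 × 8 dataset with a moderate p (~0.27), where
the χ² approximation is accurate to well under the 0.02 comparison
tolerance; at very small p the χ² approximation is known to deviate from
the exact permutation distribution by more than Monte-Carlo error, which
is a property of the approximation, not a defect of either
implementation.

## Known limitations

- The astral detector assumes rods are resolvable in the coronal
  projection; overlapping or crossing astrals (excluded by the generator,
  rare but possible in real data) would merge into one detected segment.
- Front-view central astrals are invisible to the projection-based
  detector — by design, matching the Side-view-only central counting
  rule, but it means total (three-region) censuses require Side-view
  cells.
- The cytoplasmic-background estimator (median of the eroded interior)
  assumes the cortical band is thin relative to the soma; very thick
  cortical signal would bias the background upward.
- The OU anchoring model is phenomenological; its stiffness constant is
  not derived from microtubule mechanics, and only order relations should
  be read from it.
- Tissue scenes place nuclei without overlap and with hard zone
  boundaries; nuclear crowding, zone-boundary ambiguity and staining
  variability of real sections are not modeled.
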