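# Methods

## Scope and data model

`nmjmorph` measures single en-face NMJs from two-channel, 8-bit
maximum-intensity projections with an explicit per-image calibration
(µm/pixel). One image pair = one NMJ. Obliquely oriented junctions are not
measured in 3D; the user records an `oblique_fraction` annotation and the
tool carries it as metadata. Images deeper than 8 bit are rejected unless a
linear rescale is requested, and channels are identified by an explicit
map, never by color heuristics.

## Segmentation

**Thresholding.** Both channels are binarised by a global threshold;
foreground is intensity *strictly greater* than the threshold (one fixed
convention — implementations of the same methods differ here). The default
criterion is Huang's fuzzy-entropy minimisation: for each candidate
threshold the two classes get means m₀, m₁; each gray level a membership
u(g) = 1/(1 + |g − m_class|/C) with C the intensity range; and the summed
Shannon entropy of membership, weighted by the histogram, is minimised by
exhaustive search. Yen's maximum-correlation criterion and explicit manual
values are available as overrides. Ties between thresholds break toward
the lower value, for determinism. The method and value are recorded per
image. There is no human-in-the-loop adjudication: reproducibility across
labs is the point, and provenance preserves auditability. Images that
cannot be sensibly thresholded automatically should be excluded upstream
or given a manual value.

Huang's criterion has a known failure mode worth stating: when the
background mode is *wide* relative to the foreground fraction (e.g. heavy
additive noise of constant σ), the entropy sum is minimised by splitting
the background rather than separating foreground from background. This is
a property of the criterion, not of this implementation (exhaustive search
reproduces it exactly). Realistic fluorescence backgrounds — tight around a
detector offset, with noise growing with signal — do not trigger it.

**Skeleton analysis.** The terminal mask is thinned to a one-pixel
skeleton (topology-preserving thinning; the skeleton is a subset of the
mask, contains no filled 2×2 block, and preserves the 8-connected
component count). Each skeleton pixel is classified by its count of
8-neighbours: 1 = endpoint, 2 = link, ≥3 = junction. The number of
terminal branches is the endpoint count; an isolated single pixel has no
branches. Junction pixels that are 8-adjacent are merged into a single
branch point, because thinning routinely leaves 2–3 adjacent junction
pixels at one anatomical fork; the raw junction-pixel count is also
exposed for comparison with conventions that do not merge. Skeleton length
sums steps of 1 (orthogonal) and √2 (diagonal) pixel units between
adjacent skeleton pixels, counting a diagonal pair only when the two
pixels share no orthogonal skeleton neighbour (so a right-angle corner
measures 2, not 2 + √2).

**Cluster segmentation.** The AChR plaque is resolved into discrete
receptor clusters by a marker watershed in the "segmented particles"
style: the channel is Gaussian-smoothed (σ default 1.5 px), markers are
the h-maxima of the masked image with h = `noise_tolerance` (default 10
intensity units), and a watershed on the inverted intensity, restricted to
the mask, assigns every masked pixel to exactly one cluster. The h-maxima
are computed as the textbook RMAX(HMAX) — regional maxima of the
h-reconstruction — rather than the residue-thresholding shortcut, which
fragments a single maximum whose crest plateau is interrupted by dips
smaller than h. Mask components too dim to seed any marker are kept as one
cluster each. The smoothing default of 1.5 px was chosen so that the
tolerance sits at ≈5 SD of the smoothed noise under the noise level the
synthetic benchmark uses (at σ = 1 it sits at ≈3.6 SD, and spurious
summit splits along long ridge crests are common); both parameters are
configurable.

## Morphometry

Areas are foreground pixel counts × pixel_size²; the perimeter is a
crack-boundary estimator with diagonal correction,
P = C − (2 − √2)·D in pixel units, where C counts foreground/background
pixel edges and D counts diagonal 2×2 boundary configurations (a window
with exactly two diagonal foreground pixels adds 2, with exactly three
adds 1). The estimator is exact for axis-aligned rectangles (a single
pixel measures 4) and asymptotically exact for 45° staircases; it
overestimates smooth curved boundaries by a few percent, which is
acceptable because the protocol's value lies in *comparability*, not
absolute accuracy of any single measurement.

The endplate region — the area enclosed by a perimeter around the outer
limits of all receptor clusters, traced manually in bench practice — is
automated as the convex hull of the AChR foreground by default. A hull
overestimates crescent-shaped endplates, so an alpha-shape alternative
(Delaunay triangles with circumradius ≤ 1/α kept) is available; the choice
is part of the run configuration. Endplate diameter is the maximum Feret
diameter over hull vertices of pixel centers.

The derived indices are reconstructed from their verbal definitions, each
isolated in one function so an alternative dialect is a one-line change:
complexity = log₁₀(n_branches × n_branch_points × total_length[µm]),
undefined (withheld, never recorded as 0) when any factor is zero;
fragmentation = 1 − 1/k; compactness = 100·AChR/endplate area;
overlap = 100·contact/AChR area; contact = |terminal ∩ AChR| px ×
pixel_size². Axon and fibre diameters are annotation-derived manual line
measurements, not automated mask widths. Derived fields are always
recomputed from core fields at record assembly, and records are validated
against their invariants (fragmentation ∈ [0,1), compactness ∈ (0,100],
overlap ∈ [0,100], contact ≤ min of parent areas) with the offending field
named on violation.

## Quantal analysis

Per fibre: amplitudes are scaled to a standard resting potential of −80 mV
by linear driving-force proportionality with an AChR reversal potential of
0 mV (the scaling rule is isolated in one function); the EPP is corrected
for nonlinear summation V′ = v/(1 − f·v/E) with f = 0.8 and E the driving
force at the standard potential (80 mV), defined only for v < E/f
(saturation beyond is an explicit error); quantal content = corrected EPP /
mean corrected MEPP. Whether the MEPP denominator is referred to the
standard potential or to the fibre's own resting potential differs between
descriptions of the direct method; a `mepp_reference` switch selects
(default: standard). Muscle summaries aggregate per-fibre quantal
contents (mean ± s.e.m.), never ratios of pooled means.

## Dataset statistics

PCA operates on the correlation matrix (variables z-scored) because the 11
core variables mix µm, µm² and counts; covariance-matrix PCA would let the
largest-variance unit dominate. The three-way ANOVA is a fixed-effects
main-effects model (muscle + mouse + side) with sum-to-zero contrasts and
type-III sums of squares; interactions are opt-in. Left/right comparisons
are unpaired two-sample t-tests per (muscle, mouse) pair with a Bonferroni
divisor equal to the number of pairs tested. Coefficients of variation are
computed per core variable within each sample (one muscle, one side, one
animal; ≥2 records, singletons excluded with a warning) and summarised by
their median and central 90% interval. A sampling-adequacy helper reports
cumulative means and warns when a sample holds fewer than 30 NMJs (40
recommended).

## The synthetic generator

The generator emulates the *geometry* the pipeline measures, not
microscope physics. A random planar tree is grown by random-walk segments
(0.7 px steps, Gaussian heading noise, bounded splits) whose tips carry a
leaf quota, giving a target endpoint count; the terminal mask is the tree
dilated by a terminal halfwidth, the receptor plaque a wider dilation of
the same tree, so terminal ⊂ plaque and overlap is high and stable, as at
real junctions. The plaque is carved into k clusters by deleting the bands
where geodesic cells around k seeds meet; the carved mask is opened with a
4-px disk so no cluster retains a sub-resolution neck. Geometries in which
the canonical marker watershed on a *clean* rendering cannot resolve
exactly the carved components (thin tangency necks where the arbor
approaches itself — junctions a human rater would call ambiguous) are
resampled, up to 20 attempts; the truth cluster count is always recounted
from the final mask's connected components.

Rendering: background detector offset 20, foreground 200, optional
Gaussian blur, then signal-dependent Gaussian noise whose SD is
`noise_sd` at foreground intensity and scales with √(intensity/200) —
shot-noise-like, so the background is correspondingly tighter, as in real
fluorescence micrographs. Clipped to 8 bit.

Ground truth is *measured from the pre-noise masks by the package's own
morphometry code* (skeleton statistics, hull, indices). "Pipeline matches
truth" therefore isolates exactly the imaging losses — blur, noise,
re-thresholding, marker detection — not differences between two
measurement conventions.

The default study design mirrors a 9-muscle × 3-mouse × 2-side × 40-NMJ
layout: nine profiles spread linear size ≈ ±30% (areas ≈ 3-fold) with
per-muscle cluster-count ranges whose means run ≈3.5–7.5, per-muscle mean
terminal areas of roughly 85–390 µm², axon diameters 2.3–3.3 µm tracking
muscle size, fibre diameters 18–57 µm; each mouse carries a small
lognormal size offset (σ = 0.08) and the two sides are drawn from one
distribution (no built-in side effect). Per NMJ, a latent size factor
(lognormal, σ = 0.15) scales the geometry *and* shifts axon diameter,
while fibre diameter varies at the muscle level only — so axon diameter
correlates more strongly than fibre diameter with NMJ-level size
variables, the direction comparative studies report. All randomness flows
from one master seed: NMJ (i, j, s, n) uses `SeedSequence([seed, i, j, s,
n])`, the per-mouse offset `SeedSequence([seed, 10⁶ + j])`, so any subset
regenerates identically.

What the generator does **not** emulate: point-spread-function optics,
shot-noise statistics beyond the √I scaling, uneven illumination,
out-of-focus light, labelling variability, pathological morphologies
(sprouting, denervation, faint terminals). Passing recovery tests on
synthetic data therefore demonstrates the pipeline's internal consistency
and its robustness to blur/noise at the stated levels — not performance on
degraded clinical material.

## Problem sizes and numerical choices

The statistical-recovery checks run the full default design (2160 NMJs,
truth tables, a few minutes on one core); cluster-recovery checks run 100
rendered NMJs per noise condition through the complete threshold +
watershed pipeline; permutation-uniformity of the ANOVA is calibrated with
200 replicates at 216 rows, and the left/right family-wise error with 300
replicates of 27 null pairs — sizes chosen to make the Monte-Carlo noise
small relative to the asserted margins. Floating-point determinism is
platform-local: identical inputs and config give bit-identical CSVs on one
platform. Thresholds operate on 256-bin exact histograms; criterion ties
break low; PCA uses a full SVD (no randomised solver). Degenerate inputs
fail loudly and specifically: constant images, empty masks, zero driving
force, saturated EPPs, single-level factors and constant responses all
raise typed errors naming the offending quantity.

## Known limitations

* The perimeter estimator and hull-based endplate region are conventions;
  absolute values differ from other tools' dialects by a few percent, so
  cross-tool comparisons should compare like with like.
* Branch counting by endpoints differs from segment-counting conventions;
  both the merged and raw junction tallies are exposed.
* The ANOVA treats mouse as a fixed factor; with three mice a random-effects
  treatment is underpowered anyway, but generalisation beyond the litter is
  not implied.
* Cluster counts depend on the noise tolerance and smoothing; defaults are
  calibrated for the synthetic benchmark's noise level and should be
  revisited for images with very different SNR.
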