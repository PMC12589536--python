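# Methods

## Signal model

A fiber population with in-plane orientation θ ∈ [0°, 180°) scatters
light predominantly perpendicular to the fiber axis. In an azimuthal
illumination series this produces a pair of intensity lobes at θ ± 90°
in each pixel's profile I(φ), φ ∈ [0°, 360°). The analysis inverts this:
find the peaks, match them into ~180°-separated pairs, and take each
pair's circular midline mod 180° as the fiber orientation. Up to three
pairs (three fiber populations) are extracted per pixel; more cannot be
resolved robustly in a micrometer-sized pixel.

The two antipodal midpoints of a pair coincide modulo 180°, so the
orientation is well defined even when the separation deviates from 180°
(as it does for inclined fibers). Out-of-plane inclination is not
estimated.

## Flat-field correction

Uneven illumination is measured on a diffuser plate imaged at the same
azimuths. Each diffuser image is blurred with a Gaussian of standard
deviation `blur_radius_px` (default 100 px) to homogenize plate defects
— the "radius" is interpreted as σ, the conventional parameterization
for a wide homogenizing kernel — with reflect boundary handling to keep
edge estimates unbiased. The blurred images of all angles are divided by
the average of their per-angle maxima, which fixes the normalization
invariant mean(per-angle maxima) = 1. Tissue images are divided by the
normalized diffuser of the same angle; divisors below 1e-6 of the field
maximum are masked rather than divided, to avoid amplifying sensor black
regions. The correction is exactly scale-equivariant, and for any
*separable* illumination (shared spatial pattern × per-angle gain) it
multiplies every pixel's profile by a single constant, leaving peak
positions untouched to numerical precision — the property the flat-field
acceptance test checks.

## Profile analysis

**Filtering.** Profiles sampled finer than 15° are low-pass filtered in
the Fourier domain before analysis; 15°-step series (24 azimuths) carry
only 12 harmonics and are processed unfiltered. The filter attenuates
harmonics above `cutoff × Nyquist` (default cutoff 0.40) with a
raised-cosine roll-off of relative width 0.225 centered on the cutoff;
the DC term passes untouched, so the profile mean is preserved exactly.
The raised-cosine interpretation of the "window width" is a documented
choice; any monotone roll-off with the same support behaves equivalently
for these signals.

**Peak detection.** Local maxima are found on the circular domain (the
profile is tiled three times and the middle copy analyzed, which makes
scipy's prominences equal to circular prominences) and kept when their
prominence is at least `prominence_fraction × (max − min)` of the
profile. The default of 8% is exposed in the configuration; flat
profiles yield no peaks.

**Sub-sample refinement.** Each peak position is refined as the centroid
of its lobe above the half-prominence level. The lobe is the
piecewise-linear interpolant of the samples, extended to the fractional
positions where it crosses the level, and bounded by the peak's monotone
support (the walk stops at the first valley). The support bound matters
when two lobes overlap: without it the stronger peak's half-prominence
region swallows the neighbor and the centroid lands between the two
lobes. On noise-free 15°-step phantoms this estimator is accurate to
about 0.2° for isolated lobes and degrades gracefully for overlapping
ones; it assumes roughly symmetric lobes and needs no model fit.

**Pairing.** Candidate pairs are peaks whose circular separation lies
within 180° ± 35°; the tolerance accommodates peak shifts of inclined
fibers while rejecting spurious matches. Pairs are selected greedily by
decreasing summed prominence (ties broken by ascending positions), each
peak used at most once, at most `max_populations` (default 3) pairs
kept. The greedy selection equals the lexicographically best admissible
pairing, which is what the exhaustive oracle in the test suite computes
independently. Unpaired peaks are discarded.

**Masking.** Pixels with zero mean intensity are always masked; an
optional `background_quantile` masks dim pixels before analysis
(default off, since background handling upstream of orientation
extraction is measurement-specific). Masked pixels report zero
populations.

**Conventions.** θ is measured counterclockwise from the image +x
(column) axis with the origin at top-left, reported in [0°, 180°).
Populations are stored ordered by decreasing pair prominence.

## Crossing statistics

Kernel-based crossings tile the field with non-overlapping k×k kernels
anchored at pixel (0, 0); trailing partial kernels are kept when at
least half their extent lies inside the image. A kernel's value is the
maximum population count among its unmasked pixels, and the reported
fractions are taken over kernels containing at least one unmasked pixel.
For aligned nested tilings the fraction of kernels containing a crossing
is non-decreasing in kernel size (a max over a union dominates its
parts); the kernel ladder {1, 7, 14, 71} used in the tests includes one
non-multiple step, where the property is checked empirically rather than
guaranteed.

Apparent crossings emulate a coarser detector: the raw intensities are
block-averaged (not the orientations — averaging orientations would
presuppose the answer), then re-analyzed. On scenes containing
microscopic crossing pixels, apparent crossings at a given scale cannot
exceed the kernel-based fraction at the same scale, since averaging only
loses orientation information. Note the inequality is a statement about
such scenes: a checkerboard of *single-fiber* domains has zero
kernel-based crossings by construction yet yields apparent crossings
once blocks merge — there the two statistics measure different things.

## μFODs

All orientations of all unmasked pixels in a kernel or ROI are
histogrammed into 20 bins of 9° covering [0°, 180°), mirrored to
[180°, 360°) since fiber orientations are axial. Bins are half-open
[lo, hi); θ = 180° cannot occur by the orientation-range invariant.
Counts are conserved: the μFODs of a partition's cells sum to the
whole-region μFOD. The continuous representation is an interpolating
periodic cubic spline through the bin mid-points (4.5° + 9°k) with
period 180°, evaluated on a fine grid over the full circle; an
interpolating (rather than smoothing) spline is the documented default
as it reproduces the bin counts exactly at the mid-points.

## Orientation differences

Two co-registered fields are compared through the half-circle distance
d(θa, θb) = min(|θa − θb|, 180° − |θa − θb|) ∈ [0°, 90°], a metric on
axial orientations. The default compares the dominant (best-prominence)
population of each field; a `matched` mode instead averages, over the
populations of the first field, the distance to the nearest population
of the second — useful when population order is unstable. Pixels masked
or empty in either field are excluded. The histogram uses 0.3° bins over
[0°, 90°] and is summarized by its median and by the full width at half
the modal bin's height, with the crossings located by linear
interpolation between bin centers (no parametric peak model); a side
that never drops below half clamps at the domain edge.

## Artificial diffusion dataset

Per voxel, the μFOD bin counts n_k (kernel configurable, default 1 px =
the pixel's own populations) are mapped to 63 diffusion volumes:

* 3 b = 0 ms/μm² volumes, signal 1;
* 20 in-plane directions at the bin mid-point azimuths, signal
  e^(−n_k/10) — directions rich in fibers attenuate most. The scale
  constant 10 is exposed since the normalization of the counts is a
  modeling choice;
* 20 directions in the plane containing the section normal, signal 1,
  which forbids out-of-plane fiber mass and confines the reconstructed
  distribution to the section plane. The spacing of these directions
  within that plane (9°, matching the bins) is a documented choice — only
  the plane itself matters for the constraint;
* the 20 in-plane directions tilted 20° toward the normal, signal
  1 − (1 − S₀)/5 where S₀ is the in-plane signal: the attenuation 20°
  off-axis is exactly 20% of the on-axis attenuation, a sharp fiber
  response with fast off-axis fall-off appropriate for downstream
  response-function estimation.

Signals are monotone decreasing in the bin count and lie in (0, 1];
voxels without orientations are isotropic (all 1). The slice is exported
as a 1-voxel-thick 4-D NIfTI whose header encodes the pixel size (and
slice thickness, default = pixel size) in mm, plus FSL-dialect
bval/bvec files with b in s/mm² (the downstream-tool convention; ms/μm²
is recorded in the JSON sidecar). Spherical deconvolution and streamline
tracking are deliberately external: the sidecar documents the suggested
commands (response estimation with the fa algorithm at l_max 6, CSD at
l_max 6, streamline generation with 2 mm minimum length).

## Phantom generator

The phantom emulates the azimuthal signal structure of scattering
measurements: per region, I(φ) = baseline + Σ_k A_k [g(φ − θ_k − 90°) +
g(φ − θ_k + 90°)] with g a wrapped Gaussian, optionally times a
separable illumination (spatial pattern × per-angle gain), plus additive
Gaussian noise clipped at zero (sensor floor), all driven by one seed.
Wrapped-Gaussian lobes were chosen over von Mises for closed-form peak
positions. Defaults: 24 azimuths (15° steps), baseline 1, lobe amplitude
1, lobe width σ = 6° (FWHM ≈ 14°, a strongly aligned bundle).

The lobe width bounds what the pipeline can be asked to resolve: two
equal Gaussian lobes separated by s are bimodal only for s > 2σ, and 15°
sampling needs additional margin before the inter-peak valley appears in
the samples. With σ = 6° the generator's scenes keep populations ≥ 30°
apart resolvable — the analyzer's stated operating envelope — while
σ ≳ 12° would make 30°-separated populations physically unresolvable for
any detector. The tradeoff is noise sensitivity: narrow lobes are
defined by fewer samples, so position estimates are noisier at a given
SNR (SNR here = lobe amplitude / noise standard deviation). At SNR 10
the median per-population orientation error is ~2.5°; spurious
low-prominence noise peaks also begin to inflate population counts at
this noise level, which is why the noisy acceptance check scores the
median angular error rather than count exactness.

What the phantom does *not* emulate: diffraction, inclination-dependent
peak displacement and broadening, spatially correlated noise, slide
artifacts (scratches, dust), or partial-volume mixing within a pixel.
Passing the recovery tests therefore demonstrates the correctness of the
computational chain under the stated signal model, not the physical
fidelity of the model to any particular tissue preparation.

## Problem sizes and numerics

The recovery acceptance checks run on 256×256×24 phantoms with 16-px
patches of 1–3 populations (pairwise separation ≥ 30°), noise-free and
at SNR 10; pairing is cross-checked against the exhaustive oracle on
1000 random 24-sample profiles; crossing monotonicity uses 142×142
fields so the full kernel ladder {1, 7, 14, 71} tiles meaningfully.
Degenerate inputs are defined, not exceptional: flat profiles yield no
peaks, empty regions yield zero-count μFODs with a zero spline, disjoint
masks yield an empty (flagged) difference result, and a kernel larger
than the image collapses to a single kernel. Ties in pairing are broken
deterministically by (prominence desc, position asc); mosaic subpixel
order in the orientation map is fixed by ascending θ for
reproducibility.
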