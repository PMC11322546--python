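# Methods

This note documents the models, conventions and numerical choices behind
`samquant`, and what its synthetic-data tests do and do not demonstrate
about real confocal data.

## Coordinate and sampling conventions

Grids are `(channel, z, y, x)`; `z = 0` is the top (apex-side) slice and z
increases into the tissue. Coordinates are voxel-centered: index *i* on an
axis with spacing *s* sits at *i·s* μm (0-based). All lengths are
micrometres. The default synthetic acquisition is 128×128×96 voxels at
0.2/0.2/0.4 μm, mirroring the anisotropy of typical SAM acquisitions
(sub-micron pixels, 0.4 μm z-step).

## Isotropic resampling

Quantification assumes cubic voxels, so anisotropic stacks are first
resampled along z to the xy pixel size by an interpolating cubic spline per
(y, x) column. We use a not-a-knot spline rather than a local
(Catmull-Rom-class) cubic because the not-a-knot spline reproduces
polynomials of degree ≤ 3 exactly over the whole domain, which makes the
"bicubic reproduction" property testable without boundary caveats;
Catmull-Rom derivatives are central differences and are exact only to
degree 2. Negative overshoot (possible near sharp features) is clipped to
0, preserving the non-negativity invariant of intensity data. Stacks with
fewer than 4 slices fall back to linear interpolation. Downsampling along
z (voxel_size_z < voxel_size_xy) is refused rather than silently
low-passed: it indicates inverted anisotropy metadata.

Resampling smears the tissue boundary over ~1 voxel along z. Consequently
the machine-precision concentration identities below hold on stacks that
are isotropic at acquisition; on resampled stacks the boundary voxels bias
concentration by O(surface/volume) ≈ 1–2% for the default dome sizes.

## The dome surface and the mask

The SAM surface is modelled, in a frame tilted by θ about the y axis, as
the elliptic paraboloid ζ = ξ²/c₁² + η²/c₂², apex (x₀, y₀, z₀), with ζ
pointing into the tissue. The 2D rotation is R(θ) = [[cos, −sin], [sin,
cos]] acting on (x, z) offsets from the apex; the generator and the mask
use the same matrix, so tilt conventions cannot drift apart.

**Outline fitting.** Dome outlines (explicit point lists standing in for
manually drawn curves) are fitted by rotating the points by −θ and solving
the quadratic least-squares problem, for θ on a coarse 1° grid over
[−20°, 20°] followed by bounded refinement to 10⁻³ degrees (the refinement
is three orders of magnitude cheaper than a stack operation, so there is no
reason to stop at a coarser tolerance). The selected θ minimizes the
residual sum of squares — i.e. it is the best-fitting orientation. Fits
whose quadratic coefficient is non-positive (an upside-down or degenerate
parabola) are rejected.

Identifiability caveat: over a short arc, a tilted parabola is closely
approximated by a shifted parabola at a different tilt, so θ is weakly
identified from noisy outlines. With noiseless outlines the fit recovers
apex, curvature and tilt to ~10⁻⁶; with 0.1 μm point jitter the apex can
move by several tenths of a μm through the θ–apex coupling. The recovery
guarantees asserted in the acceptance tests (apex within 1 voxel, c₁²
within 5%) therefore refer to noiseless outlines, which is also the
regime in which the geometric pipeline itself (rather than user drawing
accuracy) is being tested. A second caveat is statistical: with isotropic
jitter on the points, the ordinary least-squares curvature estimate is
attenuated by the errors-in-variables factor
(m₄−m₂²)/((m₄−m₂²)+4σ²m₂+2σ⁴) (mₖ the design moments of the abscissae),
about 3.6% at σ = 0.5 μm over a ±10 μm arc; the unit tests assert this
closed form rather than pretending the refit is unbiased.

**Mask assembly.** c₁² = 1/a_xz and c₂² = 1/a_yz; z₀ is the mean of the
two per-view apex depths; θ is taken from the xz view only (tilt is
modelled about a single axis). When the lateral (yz) view is truncated by
the acquisition, only the xz curvature is used (c₂² = c₁²); a truncated yz
parabola may still contribute its apex, otherwise y₀ must be given.

**Inflation.** Before quantification the curvature is increased,
a′ = a/α with α the image resolution in μm (α < 1, default 0.9 for 0.2 μm
pixels is deliberately mild; pass the actual resolution to reproduce a
stronger exclusion). This shrinks the mask away from the dome flanks,
excluding cell-wall autofluorescence and primordium signal. Inflation only
removes voxels, so masked totals are monotone non-increasing in it.

**Rasterization.** A voxel is interior iff its centre satisfies the
paraboloid inequality evaluated in the rotated frame — a deterministic
rule, checked against an independently coded brute-force evaluation in the
tests. No antialiasing is attempted; partial-voxel effects are part of the
2% volume tolerance discussed below.

## Concentration of fluorescence intensity

The measure is Σ(voxel intensities) / Σ(voxel volumes) over the region
between the inflated paraboloid and a transversal plane at an axial
distance d ∈ {20, 50} μm from the apex. The plane is cut perpendicular to
the *paraboloid axis* (ζ = d), not the image z axis: for a tilted dome the
quantified depth is then anatomical depth, which is the quantity of
interest; for θ = 0 the two coincide. Reported values are divided by 1000
(display convention).

For the ideal paraboloid the region volume has the closed form
π·c₁·c₂·d²/2 (area of the ellipse cross-section integrated in ζ). Voxel
counting at 0.2 μm voxels agrees within ~1%; the residual is the
half-voxel Riemann-sum excess at the apex and the staircase boundary, both
O(s) effects that shrink with voxel size.

Diffuse reporter profiles (GFP fusions) may be smoothed inside the mask
before measurement with a Gaussian filter, σ = 2.5 px by default, applied
as a mask-weighted (renormalised) convolution G·(I·M)/(G·M) so that voxels
near the mask boundary are not diluted by the zeroed exterior; a constant
region is exactly preserved. Smoothing is opt-in per profile and recorded
in the output. Total regional intensity is conserved to <1% when the
region is much larger than σ.

Linearity (scaling intensities by k scales concentration by k) and
locality (voxels outside the region never affect the measure) are exact
and property-tested. A z-uniform reporter gives the same concentration at
d = 20 and d = 50 within noise, which is the practical check that the
depth choice does not drive conclusions.

## Expression-domain geometry

Nuclear reporter domains are measured on orthogonal full-axis sum
projections of a user-cropped sub-stack (the crop excludes primordium
signal). The projection is smoothed with a σ = 1 px Gaussian before taking
its maximum — the raw maximum of a noisy sum projection is noise-dominated
— and the level set at 50% of that maximum is extracted with sub-pixel
precision by marching squares. An ellipse is fitted to the contour by
direct least squares (second-moment fallback below 6 contour points); the
axis closer to the image vertical is reported as the domain height, the
other as its width. Reported axes are FULL lengths (2× semi-axes): the
peripheral-zone formula (meristem width − WUS width)/2 is only
geometrically meaningful with full widths. A threshold region touching the
crop border raises an error instead of silently fitting a clipped domain.
The threshold is relative, so the measurement is exactly invariant to
global intensity scaling; "maximal expression" is taken per projection.
The two side views are combined by averaging height and width; per-view
values are retained.

For a Gaussian domain of width σ the half-maximum contour is an ellipse
with full axis 2σ√(2 ln 2); recovery is within 5% at 0.5 μm pixels for
σ ≥ 6 μm and converges as pixel size → 0 (checked at two resolutions).
The σ = 1 px pre-smoothing adds ⊕σ_px in quadrature — a 0.1% bias at
σ = 6 μm/0.5 μm pixels, negligible against the 5% tolerance.

## Morphometrics

Height/width landmarks are explicit inputs (the measurement is manual on
orthogonal views); the width is the distance between the endpoints placed
at the most apical visible primordium, and the height is the perpendicular
distance from the apex to the width line, which enforces the
orthogonality rule even when the drawn segment is not horizontal. The two
views of one meristem are technical replicates and are averaged; a single
available view passes through with a provenance note. Primordium identity
(vegetative / cauline / floral) is an annotation, never computed. The
meristem area is the exact sum of member-cell areas from the ingested
segmentation table (membership is derived externally from the
negative-Gaussian-curvature boundary and is taken as given). The
"maximum-height timepoint" used for cross-genotype normalization is the
argmax of the per-timepoint median height, ties broken toward the earlier
timepoint. The parabola representation y = H(1 − (2x/W)²) is the unique
downward parabola through (0, H) and (±W/2, 0).

## Statistics

Between-genotype comparisons within a timepoint use the two-sided
Mann-Whitney-Wilcoxon test: the exact null distribution when both groups
have ≤ 8 tie-free observations, otherwise the normal approximation with
mid-ranks and tie-corrected variance (scipy's implementation). No
correction is applied across timepoints, matching the reporting style the
package reproduces. Across-timepoint comparisons use classic one-way
ANOVA (equal-variance; the legends this mirrors do not specify Welch)
followed by Tukey HSD (statsmodels), summarised by an insert-and-absorb
compact letter display whose defining invariants — groups sharing a letter
have pairwise p ≥ α, groups sharing none have p < α — are asserted on
every constructed display, not assumed. Normalization divides each value
by the reference genotype's median of that measure within the same
experiment, so the reference normalizes to median exactly 1 per
experiment. Fold changes are ratios of medians. α = 0.05 throughout,
configurable.

Null calibration: simulating two n = 10 groups from one distribution over
2000 replicates rejects at ≈ 4–5%, inside [0.035, 0.065]; with n = 10 the
asymptotic branch is in use, and its continuity correction makes it
slightly conservative.

## The synthetic generator as study stand-in

The generator emulates what the measurement pipeline needs to see: a domed
surface with a cell-wall shell (Gaussian tube of thickness ~0.8 μm around
the paraboloid), diffuse interior reporters, nuclear-Gaussian domain
reporters, anisotropic voxels and Poisson(+read-noise) statistics. It does
**not** emulate cell packing, optical PSFs, depth-dependent attenuation,
bleaching or clearing artifacts — so passing tests demonstrate the
correctness of the geometry and arithmetic, not robustness to those
optical effects. Primordium bumps have compact support (truncated at 3σ)
so that crop-exclusion is exact, as a cropped-out primordium would be.

Cohort defaults encode the study conditions: wild-type medians rising from
35 to 70 μm in height and 64 to 96 μm in width between day 10 and the day-
14 peak (2-fold and 1.5-fold), and an AP2-deficient genotype ending 50%
shorter and 25% narrower at the peak; absolute medians are our choice of
realistic SAM dimensions consistent with those printed fold changes.
Plant-to-plant scatter is lognormal with σ_log = 0.12 (≈12% CV, typical of
such cohorts), n = 8 plants per genotype × timepoint, and 6 pooled
experiments (pooling across experiments is how such timecourses are
normally reported, and it keeps the sampling error of a median-based fold
change near 4%). All generators are pure functions of (spec, seed).

## Problem sizes and runtime

The test suite runs in ~15 s and the acceptance script in ~3 s on one
core: mask-recovery uses 20 domes at 128×128×96 (resampled to 191 slices),
Monte-Carlo checks use 50 replicate stacks at 40×32×32, the analytic
volume check uses a 221×221×106 grid at 0.2 μm, and the null-calibration
uses 2000 replicates. These sizes were chosen so each check's sampling
error is comfortably below the tolerance it tests.

## Known limitations

* Tilt is modelled about a single axis (y); a dome tilted in both planes
  will be fitted with a compromise θ and a slightly biased c₂².
* θ is weakly identified from short noisy outlines (see above); for real
  drawings, more points and a longer arc help more than a finer θ grid.
* The transversal plane is perpendicular to the dome axis; results differ
  from an image-z cut for strongly tilted meristems.
* Sub-voxel partial-volume effects are uncorrected; volumes carry an O(s)
  staircase bias (~1% at 0.2 μm for the default dome).
* The exact Mann-Whitney branch requires tie-free data; heavily tied
  small samples fall back to the tie-corrected approximation.
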