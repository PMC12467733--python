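# Methods

`radphantom` evaluates the geometric measurement accuracy of full-length
(cranio-caudal) radiography with a bead phantom: seven 8.00 mm steel
fiducials fixed at anatomical landmarks — chest (C), shoulders (LS, RS),
pelvis (LP, RP), hips (LH, RH) — on two coronal planes at different depths,
imaged by three acquisition principles (slot-scanning, one-shot cone-beam,
rotational stitching) across six systems.  The package contains the complete
measurement chain plus a forward simulator that generates synthetic inputs
for every stage, and reproduces the published summary statistics from the
study's printed per-pair tables.

## The measurement model

For a bead of true diameter R* = 8.00 mm whose image has pixel diameter
R_pixel on a detector with pixel size `spacing` (mm/px):

```
R_image = R_pixel × spacing                        (imaged diameter, mm)
ε_i     = mean(R_image over plane i) / R*          (plane calibration)
l       = l_pixel × spacing / ε_i                  (corrected distance, mm)
```

ε_i estimates the projective magnification of plane i; dividing by it makes
the corrected distance exactly invariant under any uniform magnification of
the acquisition.  Plane 1 holds {C, LH, RH} (nearer the X-ray source, hence
ε₁ ≥ ε₂), plane 2 holds {RS, LS, RP, LP}; only the nine within-plane pair
distances are defined — a cross-plane distance has no ε and is rejected.
The per-pair error against the CT gold standard is

```
Error = l_fulllength − l_CT            (mm)
```

and each system's error set is decomposed into MAE (mean |e|), Bias
(mean e), RMSE (√mean e²) and SD.  Under the population-SD convention
(divide by n) these satisfy the identity RMSE² = Bias² + SD² exactly, which
is how the package verifies which convention a summary table used: the
published per-system table satisfies the identity only with population SD,
while the published per-method group block reproduces only with the sample
convention (divide by n − 1).  Both conventions are therefore exposed, each
bound to the report that uses it.  Group quartiles use Hyndman–Fan type-5
(midpoint) interpolation — the published one-shot IQR [−19.19, −7.77]
reproduces under type 5 and not under the common type-7 default; type 7
remains available via `quantile_type=7`.

## Statistical design

Per-system screening uses Shapiro–Wilk (scipy's Royston AS R94) and the
zero-bias question is answered by a one-sample t test (reported only when
normality is not rejected) and the Wilcoxon signed-rank test.  The Wilcoxon
p-value is exact for n ≤ 25: zeros are dropped, tied magnitudes get
midranks, and the full 2ⁿ signed-rank distribution is evaluated by a
generating-function convolution over the doubled (hence integer) midranks —
identical to explicit sign enumeration, without the 2²⁵ cost.  An
all-one-signed sample of size n then gives the closed form p = 2·2⁻ⁿ
(= 2/512 ≈ 0.004 at the study's n = 9).

Method groups are compared with the tie-corrected Kruskal–Wallis test; the
effect size is the rank-based epsilon-squared ε² = (H − k + 1)/(N − k).
Note ε² can be slightly negative when H < k − 1 (adjusted-effect-size
behavior under the null); it is 0 exactly at H = k − 1 and bounded by 1.
Post hoc contrasts use Dunn's mean-rank differences with the tie-corrected
standard error SE = √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)],
two-sided normal p-values, Sidak family-wise adjustment
p_adj = 1 − (1 − p_raw)^m over the m = k(k−1)/2 contrasts, and simultaneous
95% CIs at α′ = 1 − (1 − α)^(1/m), so a CI excludes zero exactly when
p_adj < α.  Levene's homogeneity test is mean-centered: that variant
reproduces the study's printed p = 0.4988 to four decimals
(median-centering gives 0.4399), so mean-centering is pinned as the
default.

## Phantom reconstruction

No raw images or CT volumes are deposited, so the phantom layout is
reconstructed from the printed CT distance table.  The 3-bead plane is an
exact triangle construction; the 4-bead plane uses classical (Torgerson)
multidimensional scaling on the six distances followed by one Gauss–Newton
refinement pass — the printed distances come from a physical phantom and
are only approximately planar-consistent, and the per-pair residuals (all
< 2 mm; worst ≈ 1 mm) are recorded on the layout.  A fixed orientation
gauge (first bead at the origin, second on +x, third with +y ≥ 0; the long
anatomical axis mapped to the longitudinal direction) removes the
rigid-motion ambiguity and makes reconstruction deterministic.  The two
planes are placed 75 mm apart in depth by default; the source material is
internally inconsistent about the planes' spatial relationship, but the
75 mm figure is independently supported by the published bead diameters of
one rotational system, whose plane magnifications imply
sid(1/ε₂ − 1/ε₁) = 75.1 mm.  Everything downstream keys pairs by marker
set, never by plane number.

The synthetic CT volume rasterizes each bead as a solid sphere (voxel
centers inside the radius) on a uniform background at the scan's grid
(0.80 × 0.80 mm in-plane, 1 mm slices), with world coordinates following
the voxel-center convention (index 0 ↦ origin + spacing/2).  Gold-standard
extraction thresholds the volume (Otsu by default), labels 26-connected
components, filters them to 0.25–4× the nominal sphere volume, and fits a
sphere to each component's *surface* voxels (≥ 1 background 6-neighbor) by
the algebraic Coope least-squares form plus one geometric Gauss–Newton
step.  A centroid estimator is provided as the brute-force cross-check; on
symmetric discretizations the two agree to < 10⁻⁶ mm, and averaging fitted
centers over sub-voxel phase shifts recovers the true center within
0.05 mm.

## Acquisition geometry and what the simulator does (and does not) model

World coordinates are (x, y, z) = (transverse, depth from the focal spot,
longitudinal); the detector is the plane y = sid.  The published system
table prints its two stand-off distances as "SID/SOD" with SID < SOD for
every system, which is impossible under its own definitions (the object
must lie between source and detector, and the observed bead magnifications
require SID > source-to-bead distance); the shipped presets therefore
assign the larger number to sid and the smaller to sod.

The presets also pose the phantom `object_offset` mm source-ward of the
nominal object plane.  The published plane-mean diameters fix this: a
rotational system showing ε = 1.16/1.07 against sid/sod ≈ 1.05 must have
held the beads ~114 mm in front of the object plane.  Where the implied
offset would push the laterally asymmetric reconstructed layout off the
detector, the preset keeps a smaller value that keeps every bead in view.

**One-shot** is a plain perspective projection: magnification sid/y, exact
similar-triangles scaling for same-depth pairs.  Note a consequence the
study data confirm: an *ideal* cone-beam image of coplanar markers is
corrected exactly by its plane's ε, so the large one-shot bias observed on
real hardware must originate in undisclosed vendor processing, which this
simulator does not model.

**Slot-scanning** has two faces.  The raw analytic operator preserves the
longitudinal (scan) coordinate at unit magnification — the quasi-parallel
property — while magnifying transverse coordinates by sid/y.  Rendered
slot radiographs, however, model the image *after* the scanner's
scan-speed/scale rectification (every measured image in this workflow has
passed the manufacturer's geometric protocol): locally isotropic with
per-depth scale sid/y.  Under that model, per-plane ε calibration recovers
every within-plane distance exactly, which is the behavior the study
reports for the slot systems.

**Rotational stitching** is where a genuine, purely geometric bias
mechanism lives.  Each sub-exposure keeps the local cone scale sid/y about
its tilted central ray, but the assembly pastes segments at their
mechanically calibrated spacing — length-true at the object plane (scale
sid/sod) — and the translation-only overlap registration recovers only a
fraction (`registration_gain`, default 0.5) of the resulting parallax,
optionally with seeded jitter.  The panorama's longitudinal scale therefore
falls between sid/sod and sid/y while the bead diameters (hence ε) carry
the full local magnification: cross-segment distances are systematically
underestimated after calibration whenever the phantom sits nearer the
source than the object plane.  This mirrors the published pattern — the
most longitudinal pairs (C-LH, C-RH) carry the largest negative errors, the
transverse hip pair (LH-RH) the smallest — and the gain default is
bracketed by the study's own numbers (one system's inter-bead image scale
1.20 between its diameter scale 1.25 and its sid/sod 1.09 corresponds to a
gain of ≈ 0.7).  A featureless overlap (the bead-only render has no soft
tissue to correlate) falls back to the analytic parallax of the phantom
mid-depth plane.

Beads render as anti-aliased filled disks of diameter R*·(sid/y)/spacing;
the half-intensity contour crosses at the true projected radius, and the
sub-percent ellipticity of an off-axis sphere shadow is ignored.  Optional
noise (Gaussian intensity noise, Gaussian blur) flows through one seeded
generator per call; identical seeds give bit-identical images.  Renders in
the test-suite and default pipeline use detector grids downsampled 4× from
the published sizes (pixel spacing ×4, pixel counts /4) — at those grids
the beads are still 15–20 px across and every accuracy target is met with
margin; the full-resolution presets remain available.

## Bead detection

Within each ROI (stand-ins for the manual region selection of the original
workflow; the pipeline seeds them from render provenance), Canny edges
(σ = 1.5 px; Otsu-derived high threshold on the gradient magnitude, low =
0.4 × high) vote in a circular Hough transform over ±30% of the nominal
projected radius.  The highest-vote peak wins, ties breaking toward the
smaller radius then scan order; a 3-point parabolic fit per accumulator
axis gives sub-pixel seeds, and a radial-intensity-profile circle fit (96
spokes, half-contrast crossings, algebraic circle fit, two iterations)
polishes center and radius.  The profile refinement matters: the Hough
radius alone is quantized to ~1–3% at these bead sizes, which would
propagate through ε into multi-millimetre distance errors; with refinement
the zero-noise end-to-end chain recovers all nine distances within 0.4 mm
and stays within 1.5 mm under the tested noise levels.

The circularity metric is the fraction of accumulator votes supporting the
detected circle.  "Total votes" is normalized per radius by the circle
perimeter length (an effective edge-point count), evaluated either at the
detected radius (`single_radius`, default) or averaged over the searched
range (`radius_marginal`); both give 1.0 for a clean fully supported circle
and decrease monotonically under anisotropic stretch.  Absolute metric
values depend on this normalization choice, so only the summary arithmetic
and the monotonicity are meaningful for comparison with published values.

## What passing tests do and do not show

The synthetic generator emulates bead geometry, projective magnification,
stitching assembly and detector sampling — the quantities every computed
statistic in the workflow depends on.  It does not model scatter, detector
response, beam hardening, the phantom's soft-tissue/bone background, or any
vendor correction algorithm.  Passing the end-to-end tests therefore shows
that the measurement chain is unbiased and sub-pixel-accurate under ideal
acquisition physics, and that the stitching model reproduces the *sign and
structure* of the rotational bias; it does not certify the absolute error
magnitudes of any real system, which the study itself attributes largely to
undisclosed vendor processing.  The published summary statistics are
reproduced exactly (at printed precision) from the published per-pair
tables, which ship as fixtures; the handful of entries that cannot be
recomputed from 2-dp inputs (e.g. a MAE printed 8.05 recomputing to 8.06)
are annotated as input-rounding artifacts and compared at ±0.01.

## Numerical and degenerate-input policy

Distance tables must contain all nine canonical pairs with positive
entries; triangle-inequality violations, beads off the detector, blank
ROIs, sub-voxel bead radii, merged CT components, constant samples (W, t
undefined), empty groups and cross-plane pairs all raise typed errors
naming the offending marker or pair.  ε is computed from unrounded detected
diameters; fixture comparisons happen at the printed 2-dp precision with
half-away-from-zero rounding.  All p-values are carried at full precision
and rounded only for display.
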