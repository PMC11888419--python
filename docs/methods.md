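# Methods

This note documents the models, conventions and numerical choices
behind `ehtmech`, and what its synthetic validation does and does not
demonstrate about real recordings.

## Coordinates and regions

The tissue long axis is x (image columns), the transverse axis y
(rows). Positions are reported in mm from the fixed (non-piston) end,
where displacement is zero. Positional intervals are half-open
`[start, end)` so region assignment at boundaries is unambiguous.

The analysed portion of each tissue is the central 2.3 mm, divided into
five 0.3 mm subregions separated by 0.2 mm gaps. The central subregion
is labelled wound, its flanks border, the outermost pair remote; the
labels are symmetric about the wound midline. Separately, each zone has
a contiguous extent used for intensity integration: the wound extent is
the full 1 mm wound width, the border extent a 0.5 mm band on each side
of it, and the remote extent the rest of the tissue. The two
conventions coexist because they answer different questions: the
subregions define *where strain is sampled*, the extents define *over
what length intensity is integrated*.

## Digital image correlation

`track_displacements` is classical subset DIC: an integer-pixel
zero-normalized cross-correlation (ZNCC) search (the inner correlation
is `skimage.feature.match_template`), quadratic interpolation of the
correlation peak, then Gauss–Newton refinement of the subset
translation against the cubic-spline-interpolated deformed frame with
zero-mean residuals (a constant intensity offset between frames is
absorbed; the final reported score is the ZNCC of the refined match).
Points whose score falls below `correlation_min` (default 0.5), or
whose subset has zero variance, are invalid — never exceptions. An
optional per-point initial-guess field centres the search, which lets a
ramp analysis propagate each step's displacements to the next and keep
the search radius at ±8 px regardless of accumulated motion.

Strain uses a least-squares plane fit of u and v over the valid
neighbours within `strain_window_px` of each node, then the
Green–Lagrange formula
`Exx = ∂u/∂x + ½[(∂u/∂x)² + (∂v/∂x)²]` (and analogously Eyy, Exy), so
rigid rotations produce zero strain to numerical precision. The plane
fit needs at least three valid neighbours spanning both axes; otherwise
the node is invalid.

**Spatial resolution is the binding constraint.** Subset matching
returns approximately the mean displacement over the subset, and the
plane fit averages gradients over its window, so the effective strain
kernel has half-width ≈ `subset_px + strain_window_px`. The regional
structure of a cryowounded tissue lives at the 0.5 mm scale (wound
plateau) with 0.2 mm gaps between analysis subregions, so the kernel
must stay below ~0.2 mm. The synthetic studies therefore image at
150 px/mm (same order as the original 1920×1080 recordings of a
few-mm field) with `subset_px=12`, `spacing_px=5`,
`strain_window_px=10`, giving a ~0.15 mm kernel. At coarse resolution
(50 px/mm) the same pipeline visibly underestimates the wound modulus
because the kernel blurs the wound plateau into its stiffer-strained
neighbours — a real effect practitioners should expect, not an
artifact of this implementation.

## Geometry, stress and moduli

Widths are measured on the baseline unstretched frame at the axial
middle and both ends (transverse mask extent, median-filtered over ±2
columns) and interpolated linearly from each end to the middle — two
independent segments, exact at the three anchors. Compaction =
width / 4.0 mm (the cast width); thickness = compaction × 3.25 mm (the
culture-well height); CSA = width × thickness. Because thickness is
proportional to width, `csa(x) = width(x)² × 3.25/4` holds exactly and
is asserted as an identity. Compaction > 1 is permitted but logged as
suspect. Automatic masking uses a three-class Otsu threshold keeping
everything above the lower cut (background | tissue matrix | speckle),
with closing, largest-component selection and hole filling; a
two-class Otsu would separate speckles from matrix instead of tissue
from background. Manual width measurements can be supplied directly to
`interpolate_geometry`.

Force comes from a user-configured amperage calibration
`F(I) = Σ c_k I^k` with no constant term (so F(0) = 0, monotonicity
checked over 0–0.8 A). The default documented coefficient is 1 mN/A;
the true calibration is hardware-specific and every downstream result
is covariant with it. The synthetic ramp studies use 13 mN/A, chosen
once so the top 0.8 A step loads the remote zone (10 kPa) to 8% strain
— a realistic operating point for these gels that also keeps all zones
within the small-strain regime of subset DIC.

Stress is σ(x) = F / A(x) (mN/mm² = kPa), evaluated at each
subregion's centre, so σ·A reproduces F exactly. Strain per subregion
and ramp step is the median Exx over grid points inside the
subregion's axial window and the central 0.5 mm transverse band; the
zero-amperage frame is the strain reference, contributing an exact
(ε=0, σ=F₀/A) point. Each subregion's series is averaged within seven
uniform-width bins along its observed strain range and fit by OLS; the
slope is the modulus. Seven bins over nine ramp points means bin means
of collinear data stay collinear, so exact synthetic ramps are
recovered exactly. The alternative reading of uniform-width binning —
seven positional bins across the 2.3 mm span, each regressed
separately and averaged by zone — is available as
`binning="position"`; the default is the strain-axis reading, which is
consistent with the five fixed subregions. A modulus is defined only
when at least two occupied bins have distinct mean strains; otherwise
the fit is flagged degenerate. Zone moduli are means over the
subregions carrying each label.

## Systolic strain

Diastole (relaxed) is the reference frame, so contraction yields
negative Exx and passive stretching positive Exx. Frame selection is
automatic: within the first pacing period, diastole minimises and
systole maximises the mean tissue displacement magnitude versus the
first frame, estimated cheaply by tile-wise phase correlation over a
3×3 tiling of the tissue bounding box; sequences without motion above
a 0.1 px floor produce a warning and fall back to (first, last). The
profile is the per-grid-column median Exx over the central 0.5 mm
band, restricted to the central 90% of the long axis to avoid
restraint artefacts; zone summaries are arithmetic means over each
zone's subregion positions (gap positions excluded).

## Fluorescence intensity

Channel images are collapsed to per-column means over the tissue mask,
divided by the mean of the first 10 trace positions (the band at the
fixed-end outer edge; averaging both ends is available as
`mode="both"`), and integrated by the trapezoid rule over each zone's
extent, in mm units. AUC is computed on the normalized trace, and the
whole chain is invariant to any positive per-channel gain.
Fold-change is (AUC_t − AUC₀)/AUC₀ against the same sample's prewound
AUC, so "no change" sits at the one-sample t-test's null mean of 0.
Because the normalization band itself is never reduced (by
construction in the generator, and plausibly in reality since the
restrained ends are far from the wound), the remote fold-change is
diluted by the band fraction of the remote extent — about −0.068
recovered for a true 7.5% reduction at the default geometry.

## Statistics

`rm_anova` is a one-way within-subject ANOVA (subject = sample, factor
= zone) delegated to `statsmodels.AnovaRM` after listwise deletion,
with degenerate tables resolved from the sums of squares first: zero
zone variation → F = 0, p = 1; zero residual with nonzero effect →
F = ∞ flagged; all cells identical → flagged 0/0. Paired t-tests are
one-sample t-tests on the differences (the two are identical by
construction); zero-variance inputs return the limiting convention
(t = 0, p = 1 at the null, ±∞ otherwise) with a `zero_variance` flag
rather than raising. Significance uses the strict inequality p < 0.05
with no multiplicity correction by default, matching the reporting
convention the pipeline reproduces; Greenhouse–Geisser (from the
double-centred zone covariance) and Holm adjustments are available but
off by default. Missing cells are deleted listwise for the ANOVA and
pairwise for t-tests.

## The synthetic generator

The generator emulates the statistical and mechanical structure the
analysis assumes — not the appearance of real tissue. Speckles are
Gaussian blobs combined by maximum so coverage follows a Boolean disc
model; the blob count is chosen so the expected above-threshold
fraction equals `speckle_density` (default 0.3, a standard DIC texture
level), with centres sampled in a padded rectangle so coverage is
unbiased up to the tissue edge. Image noise is additive Gaussian per
frame (default 2% of the 8-bit range in noisy studies).

Deformation is one-dimensional: an axial strain profile is integrated
from the fixed end and applied by inverse-mapped warping (fixed-point
inversion of x + u(x), cubic interpolation), with background fill
outside the reference. The mechanical zone map centres the border zone
on the wound *edge* — the injury margin — which places zone boundaries
at the midpoints of the gaps between subregions, so each subregion
samples a single strain plateau; transitions between plateaus are
linear ramps of 0.05 mm total width confined to the gaps. In ramp mode
each zone's strain is stress divided by its modulus (ground truth
{wound 30, border 20, remote 10} kPa — a stiff necrotic core over a
softer intact gel); in beat mode the prescribed peak strains are
{wound +0.04, remote −0.03} with the border ramping linearly between
them, or all −0.02 for unwounded controls. The fluorescence zone map
uses the contiguous extents instead (the full 1 mm wound is the frozen
region), with default reductions {40%, 30%, 7.5%} applied equally to
the three channels and the edge band left at baseline.

Replicate studies add an independent per-zone relative jitter
(sd 10%) to the prescribed strains across samples, emulating
tissue-to-tissue biological variability; without it, cohort t
statistics would be dominated by sub-pixel interpolation bias rather
than any realistic variance.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates that the analysis chain is internally
consistent: correct strain math, correct region bookkeeping, correct
regression and statistics, robustness to sensor-like noise. It does
not exercise out-of-plane motion, non-affine intra-subset deformation,
illumination drift, speckle decorrelation over days in culture, or
segmentation of irregular tissue outlines — all present in real
recordings. Real-data use should treat the DIC defaults as starting
points and check the per-point correlation scores.

## Numerical choices and degenerate inputs

- Subpixel refinement: 6 Gauss–Newton iterations, updates clipped to
  ±(search+2) px of the integer solution; cubic B-spline interpolation
  with one prefilter per frame.
- Strain window: neighbours within `strain_window_px` Chebyshev
  distance (at least one grid step); rank-deficient fits are invalid.
- Binning: seven bins over `[ε_min, ε_max]` with the right edge
  inclusive; `linregress` on occupied bin means.
- Warp inversion: 10 fixed-point iterations (error O(|∂u/∂x|¹⁰),
  negligible for the ≤8% strains generated).
- Empty masks, zero-contrast frames, zero edge bands, zero CSA and
  missing study inputs raise typed errors (`ParameterError` for bad
  configuration, `AnalysisError` for failed analysis); failed
  correlations and empty subregions are flagged per-point/per-region
  instead.
- Every output CSV carries the seed and configuration hash; identical
  configuration and seed reproduce outputs byte-for-byte.

## Problem sizes

The validation studies use 4 × 4 mm tissues at 150 px/mm (ramp and
beat studies; ~640 px frames) and 50 px/mm for pure-DIC and intensity
checks, nine-step ramps, cohorts of 9 (strain) / 10 (intensity) / 20
(noisy modulus) seeded replicates, 200 random ANOVA tables and 2000
null t-test simulations. These sizes were chosen so the full
validation completes in minutes on a single CPU while keeping every
estimate's sampling error well below the tolerances being asserted.

## Known limitations

- Translation-only subset matching (no affine subset shape functions):
  first-order accurate in strain; adequate below ~10% strain at the
  resolutions above.
- Thickness is the compaction-scaled estimate, not a measurement; CSA
  inherits its error quadratically.
- The modulus is a linear-regression slope; no viscoelasticity or
  strain-stiffening is modelled.
- Frame selection assumes a regular pacing period and visible motion.
- No nucleus segmentation or cell counting; intensity is a proxy for
  cell concentration.
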