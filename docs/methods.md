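# Methods

This note documents the models, conventions and numerical choices behind
`osteotrack`, and what the synthetic phantoms do and do not establish about
behaviour on real scans.

## Scope and data model

The package analyses four kinds of raw data from a longitudinal rodent bone
study: calibrated microCT density volumes (in vivo tibia scans at 18 µm and
ex vivo scans at 7 µm), abdominal CT in Hounsfield units, Raman spectra of
embedded cortical bone over 800–1800 cm⁻¹, and three-point-bending
load–displacement traces sampled at 100 Hz. All volumes are `(z, y, x)`
arrays with isotropic voxels and an affine density calibration: two-point
hydroxyapatite (250/750 mg/cm³ rods) for bone work, or air/water standards
(−1000/0 HU) for soft tissue. Global segmentation thresholds are
300 mg/cm³ HA for trabecular and 700 mg/cm³ for cortical bone.

Because no real scans ship with the package, every stage is validated
against synthetic phantoms whose ground truth is recorded at generation
time. Generators are pure functions of their arguments including the seed
(one `numpy.random.Generator` per call, no global state).

## Longitudinal remodelling

Two registered, thresholded timepoints are differenced voxel by voxel:
voxels present only in the older mask are resorption, voxels present only
in the newer mask are formation, each expressed as a fraction of the union
(common + unique voxels). Fractions therefore lie in [0, 1] and sum with
the common fraction to 1. Metric time series are reported as percent change
versus the immediately preceding timepoint, not versus baseline.

Registration is rigid and two-stage: (1) centroid alignment, with
principal-axes alignment only when all inertia eigenvalue gaps exceed 5%
(a Gaussian-random-field structure is nearly isotropic and its axes are
noise); (2) Powell refinement of the six parameters maximising normalized
cross-correlation of the gray values. Two numerical details matter:

* NCC is scored on volumes presmoothed with a σ = 1 voxel Gaussian.
  Unsmoothed, the interpolation blur of the trial resample depends on the
  fractional part of the net transform, and NCC acquires spurious optima at
  integer voxel shifts (~0.1 voxel bias in our experiments).
* NCC is evaluated over a fixed interior core (15% margin) of the fixed
  grid, so the compared voxel set does not change with the trial transform;
  letting the valid region move with the transform biases the optimum.

With these choices the recovered transform is accurate to well under
0.1 voxel / 0.1° on noise-free phantoms. Gray values are resampled with
cubic splines; masks are never interpolated — they are recomputed by
thresholding the resampled gray volume. Trabecular phantoms use bone
600 mg/cm³ on background 0, so the 300 mg/cm³ threshold sits exactly at
the interpolation midpoint and resampling does not systematically shift
the segmented boundary.

The pipeline differences masks only where both scans have data: the part of
the fixed grid that maps outside the moving scan's field of view (plus a
2-voxel seam) is excluded. Without this, extrapolated background reads as
massive fake resorption at the borders.

### Remodelling phantom

The trabecular phantom thresholds a Gaussian random field (correlation
length 5 voxels, i.e. Gaussian σ = 2.5) at the exact quantile realising the
target BV/TV. The evolved timepoint accretes formation on the surface of
the old structure and peels resorption from it, with voxels picked
preferentially where an independent smooth random field is high — producing
contiguous patches, the voxel-scale analogue of formation packets and
resorption pits, rather than salt-and-pepper noise. Formation is placed
first (on the original surface) and resorption then peels the original
structure; the two sets are disjoint, so the realized unique-voxel counts
are exact and are recorded as truth. Old-bone voxels anchoring fresh crust
are spared from removal so formed voxels never float free. Array faces are
cuts through the structure, not physical surfaces, and are excluded from
remodelling; otherwise the fraction measured inside the field-of-view crop
differs systematically from the global truth.

Recovery on 20 seeded pairs with formation/resorption in [0.02, 0.3] is
exact pre-registration and has mean absolute error ≈ 0.01 (well under the
0.02 interpolation floor) after recovering a random rigid transform of up
to ±5° / ±3 voxels.

## Morphometry

* **Trabecular**: BV/TV is the bone-voxel fraction; Tb.Th/Tb.Sp are the
  mean maximal-sphere local thickness of bone/background;
  Tb.N = 1/(Tb.Th + Tb.Sp); BMD averages calibrated density over the whole
  VOI, TMD over bone voxels only after a one-voxel erosion (partial-volume
  suppression). Local thickness paints distance-ridge spheres in order of
  decreasing radius; the ridge includes near-maximal EDT points (within 0.5
  voxel of the local maximum) because a strict-maximum ridge is too sparse
  on discrete grids and leaves wedge-shaped gaps. On a 1 mm annulus at 7 µm
  the mean thickness is accurate to 0.5%.
* **Cortical (per slice, averaged)**: Tt.Ar from the hole-filled periosteal
  section, Ct.Ar from bone pixels, Ma.Ar their difference (the identity
  Ct.Ar + Ma.Ar = Tt.Ar is exact by construction). Major/minor axes are the
  ellipse-equivalent axes from second moments of the filled section.
  Circularity is 4πA/P² with the perimeter from marching squares on a
  lightly smoothed (σ = 2 px) mask — contouring the raw binary staircase
  overestimates the perimeter of smooth shapes by 5–8% and breaks
  circularity ≈ 1 for circles. The section modulus is I/c of the bone area
  about the medio-lateral centroidal axis, with the antero-posterior
  direction = image y-axis by convention (configurable); c extends half a
  pixel beyond the farthest bone-pixel centre. A slice whose marrow leaks
  into the background raises a broken-ring error naming the slice; a
  C-shape is distinguished from a legitimate solid rod by convex
  deficiency > 10%.
* **Adipose**: the raw abdomen scan is HU-calibrated from the air/water
  standards; the body is the largest connected component above −500 HU,
  hole-filled per slice; the mask is eroded by 1 mm (configurable, 2D disk
  per slice) to exclude skin and subcutaneous fat; adipose voxels are those
  in the −280…−150 HU window, reported as a percentage of all tissue voxels
  of the eroded mask. The abdomen phantom uses raw levels air = 10,
  water = 110 (so HU = 10·(raw − 110) is hand-checkable), adipose at
  −200 HU, lean at +40 HU, with a subcutaneous shell inside the adipose
  window that must be excluded by the erosion, and adipose blobs realising
  the target cavity fraction exactly by rank-thresholding a smooth random
  field.

Closed-form checks: the ro = 2 mm / ri = 1 mm annulus at 7 µm reproduces
Tt.Ar = 4π, Ct.Ar = 3π, Ct.Th = 1 mm and Z = π(ro⁴−ri⁴)/(4ro) = 5.890 mm³
within 2% (areas within 0.1%); a plate stack reproduces Tb.Th/Tb.Sp within
one voxel. Area errors halve (or better) from 40 µm to 20 µm voxels.

## Raman pipeline

Preprocessing: cosmic rays are flagged as residuals against a 5-point
running median exceeding 8 robust SDs (the robust scale is floored at 0.5%
of the maximum intensity so noise-free spectra do not flag their own bands)
and replaced by the mean of the nearest clean neighbours; more than 20%
flagged channels marks the spectrum unusable. Background is removed by an
iterative clipped polynomial fit (order 3 default): the fit is repeated
with the working signal clipped to it until stable, then refitted
symmetrically on background-classified channels — the clipped fit alone
hugs the lower noise envelope and sits ~1 noise SD low, which biases weak
bands by several percent. Embedding resin is subtracted as α·reference with
α fixed by the ~812 cm⁻¹ peak height ratio; negative α is clamped to zero.

Band intensities are fitted, not read off: isolated bands by a single
Gaussian plus offset in a ±10 cm⁻¹ window (amplitude bounded ≥ 0, centre
within the window), and the two overlapping doublets — proline 854/872 and
the Amide I sub-bands 1670/1690 — by joint two-Gaussian regional fits over
835–892 and 1640–1720 cm⁻¹. A raw window-maximum (retained as
`band_height(..., method="max")`) carries an upward noise bias that
dominates weak bands; fitted amplitudes are near the information-theoretic
floor. Amide I height is the larger of the two fitted sub-band heights.
Crystallinity is 1/FWHM of the v1PO₄ band with half-maximum crossings
located by linear interpolation on the lightly smoothed signal.

The seven parameters: mineral-to-matrix v1PO₄/Amide I,
carbonate/phosphate v3CO₃/v1PO₄, nanoporosity pMMA(812)/v1PO₄ measured
**before** resin subtraction (afterwards the numerator is gone by
construction — a regression test asserts the ordering), crystallinity,
hydroxyproline 872/854, GAG/Amide III 1375/1245, collagen maturity
1670/1690. All are invariant to global intensity scaling.

The spectrum generator sums Gaussians at these band positions (defaults
produce physiological ratios for rat cortical bone: MMR ≈ 10,
carbonate/phosphate ≈ 0.16, crystallinity ≈ 0.106), a polynomial baseline,
a synthetic pMMA reference dominated by its 812 cm⁻¹ peak, optional cosmic
spikes, and white noise. The default noise is 0.1% of the tallest band
(SNR ≈ 1000 on v1PO₄, representative of a 20 s × 3-accumulation
acquisition): the weakest band in the physiological regime (1690 cm⁻¹ at
~4% of v1PO₄) pins the admissible noise — at several times this level no
unbiased estimator could recover the maturity ratio to the stated
tolerances (Cramér–Rao bound). Recorded truth values are computed with the
package's own measurement operators on the clean band sum, so recovery
error isolates preprocessing and estimation fidelity: worst-case over 50
randomized spectra is ≈ 1% clean and ≈ 3% with baseline + noise.

### Line-scan distribution statistics

Per-point parameters along a periosteal-to-endosteal scan (non-bone points
excluded by a mineral-to-matrix floor of 1.0) are histogrammed (10 bins
default) and fitted with a Gaussian by least squares. The reported mean is
the histogram-weighted mean Σ XᵢFᵢ / Σ Fᵢ (the printed form "/N over bins"
is dimensionally inconsistent and reduces to this when normalised); the
FWHM is 2√(2 ln 2)·σ̂; a distribution counts as normal when the fit R² is
above 0.95. The 10-bin default deviates from finer binnings deliberately:
with ~500 points, multinomial noise alone caps the achievable R² near 0.91
at 32 bins and 0.97 at 16; about 10 bins keeps truly normal data above the
0.95 rule with margin. Even then a single draw dips below 0.95 roughly 5%
of the time, so distribution-statistics checks assert the criterion on the
median of 11 replicate draws — the appropriate reading of a
sampling-distribution claim. Degenerate inputs (constant values, < 20
points) are rejected.

## Three-point bending

Samples before the load first exceeds 1 N are trimmed and displacement
re-zeroed (machine settling). Stiffness is the maximum sliding-window
least-squares slope, window = 20% of the samples between 10% and 90% of the
ultimate load (curve smoothed by a 5-sample moving average for slope
estimation only); because that region can be dominated by a shallow
post-yield segment, a second pass repeats the estimate with the window
confined to the pre-yield portion located using the first-pass slope.
Yield follows the 10%-stiffness-loss rule: a line of slope 0.9·S anchored
at the zero-load intercept of the linear fit, intersected with the measured
curve (linear interpolation between samples); the search starts where the
curve's excess over the line peaks and stops before the failure cliff,
which always crosses the secant and must not masquerade as yielding. With
no crossing the ultimate point is returned flagged. Failure is the first
sample after the ultimate where load drops below 10% of the running
maximum; work-to-fracture integrates the raw curve to that point
(trapezoid); post-yield displacement is the difference of failure and yield
displacements. Material coupling: peak moment = F·L/4 for a central load
over the 15 mm span, tissue strength = peak moment / section modulus
(N·mm/mm³ = MPa), with Z supplied by the cortical morphometry stage.

The curve generator is piecewise linear (elastic slope S to a programmed
kink, hardening slope k to the ultimate, plateau, abrupt drop) and records
both the kink and the analytic 10%-rule crossing load — the latter is what
the detector estimates, and for a plateau the two coincide. Recovery of
stiffness/yield/ultimate/work over 20 randomized curves with 0.2 N noise is
within 0.7% (tolerance 2%).

## Group statistics

A Brown–Forsythe test (median-centred Levene) gates the branch: equal
variances → one-way ANOVA with Dunnett tests versus the control group
(Tukey HSD available as an option; Dunnett's multivariate-t integration is
seeded for reproducibility), otherwise Kruskal–Wallis with Dunn's
rank-based post hoc comparisons, Holm-adjusted (implemented in-package:
tie-corrected z on pooled mean ranks). Shapiro–Wilk normality of the pooled
residuals is always reported and can optionally join the gate. The null
rejection rate of the gated omnibus test is calibrated: 0.045–0.053 at
nominal α = 0.05 over 1000 replicates of three n = 10 normal groups.
Cross-modality agreement (e.g. in vivo vs ex vivo BV/TV) uses ordinary
least-squares regression with R² and slope p-value.

## What the phantoms do not establish

The phantoms have sharp two-level densities, no beam hardening, ring
artefacts, scanner noise or anatomical anisotropy; registration accuracy
and the remodelling interpolation floor on real scans will be worse.
Trabecular/cortical contouring on real anatomy is out of scope — phantoms
carry their contour by construction, and the growth-plate landmark is an
input, not detected. Raman truth is defined through the package's own
band-measurement operators; absolute accuracy against a different intensity
convention (integrated areas, fixed-position heights) is not claimed. The
bending curves contain no machine compliance or toe-region curvature beyond
the preload ramp.

## Problem sizes

Default study-scale runs: 48³–64³ voxel trabecular phantoms (18 µm), the
7 µm annulus at ~675 k voxels, abdomen phantoms at ~1 M voxels, 1001-channel
spectra, ~14 000-sample bending curves, 20-pair / 50-spectrum / 20-curve
recovery cohorts and 1000-replicate statistical calibration. The full test
suite runs in ~3 minutes on one CPU; `scripts/acceptance.py` in ~2 minutes.
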