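# osteotrack

Analysis pipeline for longitudinal rodent bone studies that combine in vivo
and ex vivo microCT, Raman microspectroscopy and three-point bending —
the measurement chain typically used to follow skeletal changes after
bariatric surgery, diet intervention, or pregnancy/lactation in rats.

It is aimed at bone researchers who have the raw instrument outputs
(calibrated density volumes, wavenumber/intensity tables, load–displacement
traces) and want the derived quantities those studies report, with every
computational step testable against synthetic phantoms of known ground
truth.

## What it computes

**Longitudinal remodelling** — two registered, thresholded microCT
timepoints are differenced voxel by voxel: voxels present only in the older
scan are resorption, voxels only in the newer scan formation, each divided
by the union of the two bone masks,

    formation = |new \ old| / |old ∪ new|,   resorption = |old \ new| / |old ∪ new|

with rigid registration (principal axes + normalized cross-correlation
refinement), growth-plate-referenced volumes of interest, and %-change
time series versus the previous timepoint.

**Morphometry** — trabecular BV/TV, Tb.Th, Tb.Sp (maximal-sphere local
thickness), Tb.N, BMD; cortical Tt.Ar, Ma.Ar, Ct.Ar, Ct.Ar/Tt.Ar, Ct.Th,
TMD, ellipse-equivalent major/minor axes, circularity 4πA/P², and the
section modulus Z = I_ML/c_AP about the medio-lateral bending axis;
HU-calibrated abdominal adipose percentage (−280…−150 HU window, skin and
subcutaneous fat excluded by mask erosion).

**Raman bone material properties** — despiking, iterative polynomial
background removal, pMMA embedding-resin subtraction scaled on the
~812 cm⁻¹ resin peak, and seven band-ratio parameters: mineral-to-matrix
(v1PO₄/Amide I), carbonate/phosphate (v3CO₃/v1PO₄), nanoporosity
(pMMA/v1PO₄, measured before resin subtraction), crystallinity (1/FWHM of
v1PO₄), hydroxyproline/proline (872/854), GAG/Amide III (1375/1245) and
collagen maturity (1670/1690); line-scan histograms summarised by weighted
mean, Gaussian-fit FWHM and the R² > 0.95 normality rule.

**Three-point bending** — stiffness (max sliding-window slope), yield by
the 10%-stiffness-loss secant rule, ultimate load, post-yield displacement,
work-to-fracture, and the material coupling peak moment = F·L/4,
tissue strength = M/Z in MPa.

**Statistics** — Brown–Forsythe-gated one-way ANOVA/Dunnett (or Tukey)
versus Kruskal–Wallis/Dunn with Holm adjustment, and OLS cross-modality
regression.

The `synthgen` module generates every input type with recorded ground
truth: Gaussian-random-field trabecular phantoms at a target BV/TV, evolved
timepoints with exactly counted formation/resorption voxels, annular
cortical phantoms with closed-form areas and section modulus, an abdomen
phantom with air/water standards, band-sum Raman spectra and
piecewise-linear bending curves.

## Worked example

```python
from osteotrack import synthgen, remodel, morphometry, biomech, raman

# two timepoints with known remodelling, differenced on a common grid
vol, _ = synthgen.make_trabecular_phantom((48, 48, 48), voxel_size_um=18.0,
                                          target_bvtv=0.25, seed=7)
vol2, truth = synthgen.evolve_phantom(vol, formation_fraction=0.10,
                                      resorption_fraction=0.05, seed=3)
result, log = remodel.remodel_pipeline(vol, vol2, register=False)
print(f"formation {result.formation_fraction:.4f} (truth {truth.formation_fraction:.4f})")
print(f"resorption {result.resorption_fraction:.4f} (truth {truth.resorption_fraction:.4f})")

# cortical geometry of a 2 mm / 1 mm annulus at 7 um voxels
ring, ring_truth = synthgen.make_cortical_phantom(2.0, 1.0, voxel_size_um=7.0, n_slices=2)
m = morphometry.cortical_metrics(ring)
print(f"Ct.Ar {m.ct_ar:.3f} mm^2 (3*pi = {ring_truth.extras['ct_ar_mm2']:.3f})")
print(f"Z {m.section_modulus:.3f} mm^3 (analytic {ring_truth.extras['section_modulus_mm3']:.3f})")

# bending curve analysed against that section modulus
curve, _ = synthgen.make_load_curve(stiffness=650, yield_load=130, postyield_slope=60,
                                    ultimate_load=170, failure_displacement=1.2, seed=0)
res = biomech.analyze_curve(curve, span=15.0, section_modulus=m.section_modulus)
print(f"stiffness {res.stiffness:.0f} N/mm, yield {res.yield_load:.1f} N, "
      f"ultimate {res.ultimate_load:.1f} N, tissue strength {res.tissue_strength:.1f} MPa")

# one synthetic bone spectrum through the full Raman pipeline
spectrum, s_truth = synthgen.random_spectrum(seed=1)
params = raman.compute_params(spectrum, synthgen.pmma_reference())
print(f"mineral/matrix {params.mmr:.2f} (truth {s_truth.mmr:.2f}), "
      f"crystallinity {params.crystallinity:.4f}")
```

prints

```
formation 0.1000 (truth 0.1000)
resorption 0.0500 (truth 0.0500)
Ct.Ar 9.426 mm^2 (3*pi = 9.425)
Z 5.894 mm^3 (analytic 5.890)
stiffness 650 N/mm, yield 131.4 N, ultimate 170.8 N, tissue strength 108.7 MPa
mineral/matrix 7.39 (truth 7.38), crystallinity 0.1041
```

The remodelling fractions recover the generator's recorded truth exactly on
a common grid; the annulus areas and section modulus match the π-formulas
to a few tenths of a percent; the bending estimates recover the programmed
curve (the yield of 131.4 N is the analytic 10%-stiffness-loss crossing,
slightly above the 130 N kink); the Raman ratios match the construction
values of the spectrum within the noise.

A command-line interface mirrors the library
(`osteotrack remodel|morpho|raman|biomech|run|demo`); `osteotrack demo`
writes a full synthetic three-group cohort with tidy CSV outputs and group
statistics.

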