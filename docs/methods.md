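# Methods

## Forward model

Blood absorption is modelled per band as

  μa_BV(λ) = ln(10) · B · [εoxy(λ)·SO₂ + εdeoxy(λ)·(1 − SO₂)]   (cm⁻¹)

with B the total hemoglobin molarity and ε the decadic molar extinction
coefficients. Conventions: extinctions are base-10 (so μa carries the
ln 10 factor) and all absorbances are base-10. Each of the 23 acquisition
bands (500–720 nm, 10 nm pitch, ~7 nm bandwidth in the physical
instrument) is treated as a delta function at its center wavelength; band
integration would smooth the sharp 540–580 nm structure slightly but
changes nothing qualitative at 10 nm sampling.

Defaults: B = 150 g L⁻¹ / 64 500 g mol⁻¹ ≈ 2.326×10⁻³ M (physiological
whole blood). Arterial and venous presets are SO₂ = 0.98 and 0.75.

### Extinction table

No network access is assumed at build or run time, so the package vendors
a *synthetic* compilation (`data/hemoglobin_extinction_synthetic.csv`,
450–1000 nm at 1 nm): literature-typical anchor values — the Soret tail,
the oxyhemoglobin 542/577 nm double peak with the 560 nm trough, the broad
555 nm deoxy peak, the ≈10:1 deoxy/oxy ratio at 660 nm, the ≈800 nm
isosbestic point — densified by shape-preserving PCHIP interpolation
(`scripts/build_extinction_table.py` regenerates it). Magnitudes are
representative rather than metrologically traceable; because the same
table drives both forward simulation and inversion, every round-trip,
shape and ratio result in this package is exact by construction, while
absolute absorbance values should not be compared against other tables.

## Monte Carlo transport

Standard layered-slab packet transport: exponential free paths with
μt = μa + μs, implicit-capture weight deduction μa/μt per collision,
Henyey–Greenstein scattering, unpolarized Fresnel reflection/refraction at
every index-mismatched interface, and Russian roulette below weight 10⁻⁴
with survival probability 0.1. Specular reflection at the top surface is
computed analytically and excluded from the diffuse tally. z increases
downward from the illuminated surface; vessel depth is measured to the top
of the vascular layer.

Roulette bookkeeping is weight-exact rather than only unbiased: a kill
credits the packet weight to the absorbed tally, a survival debits
w(1−p)/p. Consequently specular + reflected + transmitted + escaped +
absorbed equals the launched weight to float rounding on every run, which
the tests assert at 10⁻⁶.

Beam and detection: flat 4 cm beam at normal incidence, 0.1 J nominal
energy (fractions are energy-normalized). Detection integrates all weight
exiting the top/bottom surface within a co-axial aperture defaulting to
the beam radius; exits outside the aperture are tallied separately
(`escaped_fraction`), and a 100-bin × 0.05 cm radial exit profile is kept
as a diagnostic. With an unbounded aperture the escaped term is zero and
the four-way identity holds exactly.

Randomness: one master seed; per-(band, model) streams are derived with a
splitmix64 hash, so sweeps are reproducible and order-independent.
Consecutive integer seeds are never used for replicate streams (Mersenne
Twister states seeded consecutively are noticeably correlated; the hash
avoids that).

## Layered skin model

The published per-layer parameter tables behind the original simulation
study are not available, so the default model uses literature-typical skin
optics *for the visible band*, all overridable:

| layer      | thickness | μa (cm⁻¹) | μs (cm⁻¹) | g   | n   |
|------------|-----------|-----------|-----------|-----|-----|
| epidermis  | 0.01 cm   | 10        | 150       | 0.8 | 1.4 |
| dermis     | variable  | 2.0       | 120       | 0.9 | 1.4 |
| vascular   | 0.05 cm   | from blood| 120       | 0.9 | 1.4 |
| dermis     | to 0.3 cm | 2.0       | 120       | 0.9 | 1.4 |

The absorption values matter: at 500–720 nm epidermal melanin and the
dermis' baseline blood content make skin far more absorbing than in the
NIR window, giving an effective penetration depth below a millimetre
(μeff ≈ √(3 μa (μa+μs′)) ≈ 13 cm⁻¹). That penetration depth is precisely
what separates the two detection geometries — with an (unphysical for
this band) transparent dermis, reflective detection would still resolve a
vessel at 1–2 mm and the geometry comparison would lose its subject.

The vascular layer is *perfused tissue*, not bulk blood: its absorption is
f·μa_blood(λ) + (1−f)·μa_dermis with blood volume fraction f = 0.05 by
default (a literature-typical dermal plexus value). This matters: a 0.5 mm
layer of whole blood is ~13 natural optical depths at the green hemoglobin
peaks, which saturates the detected spectrum and destroys the linear
Beer–Lambert regime that band-ratio oximetry relies on — no realistic
instrument would recover surface SO₂ under those conditions, whereas a
perfused layer reproduces the expected behaviour (accurate reflective
reads at the surface, stable transmissive reads through 2 mm). The
background model is the identical stack with the vascular layer's
absorption set to the dermis value.

Because depth curves therefore depend on chosen defaults, depth and
sensitivity results are asserted as *trends and ratios* (monotone
amplitude decay, acceptance through 2 mm, fold-ratio of errors), never as
absolute curve values.

## Unmixing

Vessel absorbance per band is A(λ) = log₁₀(background/sample) of the
detected fractions (or of corrected pixel ratios). The modified
Beer–Lambert design matrix X = [1, εoxy, εdeoxy] is solved by NNLS with
*all three* coefficients constrained non-negative (the offset ξ absorbs
non-hemoglobin losses and is physically a loss, hence ≥ 0);
SO₂ = C₂/(C₂+C₃). Goodness of fit is the Pearson correlation between
measured and fitted spectra over the usable bands; fits with r < 0.9 are
rejected, as are fits with C₂+C₃ = 0 (no hemoglobin signature). Bands
with non-positive fractions (opaque vessel or Monte Carlo starvation) are
flagged non-detectable and excluded from fit and correlation; spectra
with fewer than 10 usable bands of 23 are rejected outright (the cutoff
is this package's choice). Rejections carry reason codes (`low_r`,
`no_hemoglobin`, `bad_bands`) rather than sentinel values.

Degenerate inputs: constant spectra have zero variance, so the Pearson
statistic is undefined — such pixels reject via the no-hemoglobin path
(flat spectra are fit entirely by ξ).

## Imaging pipeline

Real stacks are corrected per pixel and band as
(I − I_dark)/(I_ref − I_dark), then ratioed against the identically
corrected background spectrum; the background spectrum is the per-band
*median* over a user-supplied avascular ROI (median for robustness to
stray vessels — how the background is obtained for real images is this
package's choice; an explicit spectrum can be passed instead). Mapping is
pixel-independent, hence order- and transposition-equivariant.

Dynamics: per-vessel SO₂ per time point is reduced from a vessel ROI by
the median of accepted pixels. ΔSO₂(t) = (Sᵢ − S_BL)/S_BL against the
pre-stimulus baseline mean. Peak response is the maximal decrease at or
after stimulus onset; recovery time is the first return to baseline after
the trough, linearly interpolated between samples and requiring two
consecutive at-or-above-baseline samples (a guard against noise-triggered
early recovery; the requirement is this package's choice). A series that
never recovers yields `None`.

Annuli: 0.5 mm rings from 0 to 4.5 mm around a floating-point
(row, col) center; membership by pixel-center distance; means over
accepted pixels only; empty rings carry NaN. Tumor region ≤ 3 mm,
adjacent 3–4.5 mm.

## Synthetic phantoms

The phantom emulates a 2 mm intralipid bath (μs′ = 10 cm⁻¹ at 550 nm with
1/λ scaling, μa = 0.02 cm⁻¹, g = 0.7, n = 1.33) with a 0.5 mm blood-filled
capillary inserted diagonally so depth ramps 0.05→2 mm along the image.
Two fidelity levels generate the background transmission: a 1-D diffuse
attenuation ('fast', exp(−μeff·d), seconds) or cached Monte Carlo sweeps
of the homogeneous bath ('mc'). Vessel pixels are attenuated by the
forward-model absorbance over the local cylinder chord; in reflective
mode the vessel contrast additionally decays as exp(−depth/0.35 mm),
a phenomenological stand-in for shallow photon sampling. Multiplicative
Gaussian noise (σ = 0.01 typical) and a dark offset complete the frames.

What the phantom does *not* emulate: diffusive path-length dispersion
(vessel attenuation is single-chord Beer–Lambert), partial-volume edge
pixels, motion, spatially structured illumination, or camera shot-noise
statistics. Closed-loop recovery on phantoms therefore validates the
pipeline's algebra, masking and geometry — not the accuracy of the
modified Beer–Lambert model under multiple scattering, which is exercised
separately by the Monte Carlo studies.

## Study drivers and problem sizes

The depth study runs paired sample/background sweeps per (depth, mode,
preset) cell and unmixes each; background sweeps are shared across presets
at a depth. The sensitivity analysis ramps presets 98→50% and reports the
least-squares slope of recovered-vs-preset SO₂ per (depth, mode), the mean
absolute error of recovered relative change (baseline 98%), and the
reflective/transmissive error fold-ratio per depth. Cells rejected by the
Pearson gate contribute a recovered change of zero — an instrument that
reports nothing detects no change — and are counted.

The sensitivity analysis uses common random numbers: every preset on the
ramp (at a given depth) reuses the same derived photon stream, and the
background sweep is likewise shared. Relative changes are differences of
correlated estimates, so common-mode Monte Carlo noise cancels and the
error ratio measures the systematic (detection-geometry) component rather
than the noise realization — the standard variance-reduction design for
difference estimands in simulation studies. (Correlation is partial: the
vascular layer's per-preset absorption alters step lengths inside the
vessel, after which photon paths diverge; empirically the cancellation
still roughly halves the transmissive-mode error.)

Default problem sizes are chosen for a single CPU core: 10⁵ photons per
band for acceptance-grade runs (the package's standard study size) and
10⁴ for quick looks; tolerances in the test suite are set for these sizes.
Monte Carlo noise scales as 1/√N as verified by the variance tests.

## Known limitations

- Absolute absorbances depend on the synthetic extinction compilation and
  on skin-model defaults standing in for unavailable published tables;
  only shapes, trends and ratios are transferable.
- The modified Beer–Lambert inversion is negatively biased under diffuse
  transport (path-length dispersion); a lookup-table inversion built on
  the transport code would remove this but is out of scope.
- The planar vascular layer ignores cylindrical vessel geometry in the
  transport study (the cylinder appears only in the imaging phantom).
- No polarization, fluorescence, or time-resolved transport; no motion
  artifacts or vessel segmentation in the pipeline (ROIs are
  user-supplied).
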