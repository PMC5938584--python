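# Methods

`iriscale` models the chain from butterfly wing-scale nanostructure to
perceived colour: a one-dimensional multilayer reflector inside the scale
ridges produces an iridescent reflectance band; the spacing of the ridges
sets how much of the wing is covered by reflectors and hence how bright the
wing is; and a receptor-noise-limited visual model scores how discriminable
two wings are to a bird or butterfly observer. This note documents the
models, the tunable parameters, the synthetic-data generators used in place
of instrument data, and the numerical choices.

## Multilayer optics

The ridge lamellae are treated as a periodic stack of homogeneous,
non-absorbing slabs between an air ambient and a chitin substrate (the body
of the ridge). The default stack is the measured iridescent-ridge geometry:
a unit cell of 119 nm air (n = 1.0) over 85 nm chitin (n = 1.56), repeated
twice — the number of regular chitin protrusions seen in ridge cross
sections. Two predictions are implemented.

**First-order interference condition.** The first-order reflectance maximum
of the unit cell at incidence θ is

    λ₁ = 2 Σᵢ dᵢ √(nᵢ² − sin²θ),

which at normal incidence reduces to twice the optical thickness of the
period. For the default stack this gives λ₁ = 2(1.0·119 + 1.56·85) =
503.2 nm, and the thickness-weighted mean index is
n_eff = (1.0·119 + 1.56·85)/204 = 1.2333. (A slightly lower effective
index, 1.22, is sometimes quoted for this geometry; the averaging rule
behind that value is not derivable from the stated thicknesses and index,
so the package uses the plain thickness-weighted mean and documents the
~1% difference, which moves λ₁ by ~5 nm — within the measurement
uncertainty band of ±18 nm either way.)

**Transfer-matrix reflectance.** The exact characteristic-matrix solution
for the finite stack, for s and p polarization (unpolarized = their mean).
Indices are real and wavelength-independent; absorption by melanin in the
ridge is deliberately excluded from the interference calculation (an
imaginary-index hook exists but defaults to zero) because the quantitative
claim being modelled is a lossless interference peak. Verified against
closed forms: the Fresnel single-interface reflectance, the quarter-wave
stack formula, reciprocity, energy bounds, and convergence of the TMM peak
to the first-order condition as index contrast → 0.

## Ridge-spacing estimation

**SAXS route.** Detector pixels map to momentum transfer via
q = (4π/λ) sin(θ) with 2θ = atan(r/D); the default geometry is 0.1 nm
X-rays at D = 30.98 m, 0.1 mm pixels on a 192×192 grid (a downscaled
detector that keeps the ring of every plausible ridge spacing,
500–1500 nm, well inside the frame). Radial integration averages masked
intensity into equal-width q bins. The spacing peak is isolated by fitting
a single power law I = A·q^(−m) to the regions flanking a configurable
q window (default 2π/1500 … 2π/500 nm⁻¹), subtracting it, taking the
maximum of the residual inside the window with 3-point parabolic
refinement, and returning d = 2π/q_peak. A window maximum that sits on the
window edge, or does not exceed three times the RMS background-fit
residual, raises a no-peak error rather than returning a number.

**AFM route.** The height map is de-trended by removing its best-fit
plane, Hann-windowed, and Fourier transformed; the 2-D power spectrum is
azimuthally integrated into radial-frequency bins one FFT bin wide. The
dominant non-DC bin inside the expected spacing window is then refined by
the power-weighted centroid of spatial frequencies within ±2 bins of it —
Hann-window leakage is symmetric about the true spectral line, so the
centroid removes most of the bin-quantization error (≤0.3% across
spacings of 723–1253 nm on a 512-pixel, 10 µm scan, versus up to ~4% for
the raw peak bin). Azimuthal integration makes the estimate invariant to
in-plane rotation of the ridge pattern; the peak bin must carry at least
twice the mean in-window power, otherwise a no-peak error is raised.

On paired synthetic data generated from a single ground-truth spacing the
two estimators agree within 0.5%, the pipeline-level analogue of reporting
the two spacing columns side by side.

## Spectrum processing

Spectra are percent-of-white-standard reflectance on a strictly increasing
nm grid; the working range for all summary statistics is 300–700 nm (the
bird/butterfly visible range) and the default resampling grid is 1 nm with
inclusive endpoints. The processing chain is linear interpolation onto a
common grid, LOESS smoothing, and min-zero normalization. The smoother is
a local quadratic regression with tricube weights whose `span` parameter
is the fraction of points in the local window (default 0.3); any negative
smoothed value is clamped to zero *after* smoothing (fix-negatives-to-zero
semantics). Exact parity with any external smoothing package is a
non-goal: acceptance is recovery of generator ground truth.

Peak wavelength is the argmax in the working range; FWHM interpolates the
two half-maximum crossings flanking the peak and is reported missing
(flagged, not extrapolated) when a crossing falls outside the range. A
peak on the range boundary is flagged as such — this is how non-iridescent
wings, whose reflectance still rises at 700 nm, are reported as "~700"
with no FWHM. The angle of maximum reflectance is the angle whose spectrum
attains the global maximum; ties break toward the smaller absolute angle
(a reproducibility rule with no physical claim), and an optional quadratic
refinement over the three bracketing angles is off by default.

Peak-location accuracy under noise is amplitude-limited: with 0.5%
instrument noise the peak of a Gaussian band of amplitude ≥6% is recovered
within 2 nm after smoothing, but at ~1% amplitude (the dimmest taxa) the
curvature signal near the peak is far below the residual noise and the
location scatters by ~10 nm whatever the smoother — consistent with those
taxa reporting no measurable peak at all. Tests assert the 2 nm recovery
only where the peak is identifiable.

## Receptor-noise visual model

Receptor sensitivities are built from the Govardovskii A1 pigment template
(α band plus β band) at each receptor's λmax and normalized to unit peak —
standard practice when only λmax values, not measured curves, are
available. Because the built-in sensitivities, the canopy illuminant and
the ocular-media curve are approximations rather than the original
recordings, absolute JND values for real wings are not reproduction
targets; all acceptance on this module is property-based plus a fixed
synthetic regression.

Quantum catches are trapezoidal integrals on the 1 nm grid of reflectance
(as a fraction of the white standard) × sensitivity × illuminant ×
ocular-media transmission. Von Kries normalization divides each catch by
that of a perfect white reflector under the same illuminant, so the
adapting white maps to unit catches; von-Kries relative catches are used
for colour-space coordinates, absolute catches for discriminability (the
choice is immaterial for the chromatic JND, which depends only on catch
ratios). Illuminants: the CIE D65 tabulation restricted to 300–700 nm, and
a stylized "forest shade" built as D65 attenuated by a Gaussian
green-transmission band (centre 550 nm, width 90 nm, 10% broadband floor)
— UV- and blue-poor with a green-yellow maximum, the defining features of
canopy light. The avian system additionally applies a smooth logistic
ocular-media cut-off near 320 nm approximating a passerine eye (toggleable;
oil-droplet filtering is not modelled).

Five built-in observers: avian violet-sensitive (λmax 416/478/542/607 nm,
Weber fraction 0.06, abundances 0.25/0.5/1/1) and *Heliconius* types I–IV
(Weber fraction 0.05; type I 355/390/470/555 with 0.09/0.07/0.17/1,
type II 390/470/555 with 0.13/0.2/1, type III 355/390/470/555 with
0.09/0.13/0.2/1, type IV 355/470/555 with 0.07/0.26/1). Abundances can
also be derived from ommatidial-type statistics (type fractions × within-
type receptor proportions, normalized to the L receptor).

Discriminability uses log-coded signals Δfᵢ = ln(Q_a,i/Q_b,i) and noise
eᵢ = w·√(η_L/ηᵢ) with the long-wavelength receptor (η = 1) as the
reference, so e_L = w. The chromatic JND uses the closed-form dichromat,
trichromat and tetrachromat expressions of the receptor-noise model; the
tests verify them against the general matrix form (the noise-weighted
Mahalanobis length of Δf projected off the achromatic direction). The
achromatic JND is |Δf_L|/w. Colour coordinates embed relative catches as
convex combinations of regular-simplex vertices (Maxwell triangle for
trichromats, tetrahedron for tetrachromats) placed 0.75 from the centroid,
so a single-receptor stimulus sits on a vertex and equal catches at the
achromatic origin.

## Synthetic data

Generators are pure functions of (parameters, seed); all randomness flows
through `numpy.random.default_rng(seed)`.

* **Angle series**: per-angle unpolarized TMM reflectance of a stack ×
  Gaussian angular envelope (default centre 10°, width 15°) × an amplitude
  scale (default 30.6%, the brightest measured wing), plus Gaussian noise
  (default σ = 0.5%) clipped at zero. The spectral peak blue-shifts away
  from the envelope centre, reproducing goniometer phenomenology.
* **SAXS frames**: isotropic Gaussian ring at q = 2π/spacing (width 4% of
  q₀) over an A·q⁻² background, Poisson-sampled (photon counting), with a
  central beam-stop mask. Geometry defaults to the experiment being
  emulated (0.1 nm, 30.98 m).
* **Height maps**: sinusoidal parallel ridges (default height 150 nm over
  a 10 µm, 512-pixel field), optional smooth cross-ridge curvature and
  along-ridge saw-tooth discontinuities, Gaussian roughness (σ = 5 nm).
* **Co-mimic fixture**: two 4-individual groups of spectra from stacks
  whose periods differ by 8 nm (split evenly between air and chitin
  layers), with seeded noise — a desk-scale stand-in for comparing
  co-mimetic wings, used only for reproducible-ordering regressions, not
  biological claims.
* **Summary-table fixture**: the transcribed per-taxon value set (eight
  taxa) used by the reporting stage.

What the generators do *not* emulate: real wings are curved, spatially
heterogeneous mosaics of scales with melanin absorption, disorder in layer
thickness and ridge spacing, and cross-rib scattering; SAXS patterns of
real scales are anisotropic with multiple structure peaks; AFM scans carry
tip-convolution and line-registration artefacts. Passing round-trip tests
therefore shows the estimators are correct on their stated signal model,
not that they are robust to every artefact of real instruments.

## Statistics

Per-taxon summaries report across-individual means with sample (n−1)
standard deviations; a single individual yields no s.d. The
spacing-brightness association is a Pearson correlation of per-taxon mean
SAXS spacing against mean maximum reflectance (taxa lacking either value
are dropped; n = 7), with the two-sided p from t = r√((n−2)/(1−r²)); the
tests confirm this p against an exhaustive 5040-permutation oracle to
within 0.01. Clade slopes are ordinary least squares within the configured
erato and melpomene groupings, reported as a directional contrast only —
no formal slope-difference test and no multiple-testing correction (a
single planned test). The correlation on the bundled table reproduces
r = −0.829, p = 0.021.

## Problem sizes

Defaults were chosen so the whole test suite runs in seconds while staying
inside the regimes the estimators are designed for: 192² SAXS frames
(~37 k pixels, ring radii 24–43 px), 512² height maps with 7–14 ridge
periods per scan, 401-point spectra, 16-pair discriminability blocks.

## Known limitations

* Lossless, dispersion-free optics: no melanin absorption in the
  interference calculation, no wavelength-dependent indices, and no
  electromagnetic treatment of curved lamellae (curvature enters only as a
  statistical feature of synthetic height maps).
* The LOESS smoother matches the cited processing semantics but not any
  specific implementation bit-for-bit.
* Visual-system curves are templates; absolute JNDs for real wings should
  not be read off this model without the original sensitivity recordings
  and illuminant tabulations.
* The SAXS background model is a single power law; profiles with multiple
  structure peaks (lamellar periodicity, cross-ribs) are out of scope —
  only the ridge-spacing peak is extracted.
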