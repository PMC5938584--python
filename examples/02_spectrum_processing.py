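"""Processing an angle-resolved reflectance series.

Generates a synthetic goniometer series for the brightest iridescent taxon
(multilayer reflectance shaped by a Gaussian angular envelope plus
instrument noise), runs the standard processing chain (smooth, clamp
negatives, min-zero normalize) and extracts the summary descriptors: angle
of maximum reflectance, peak wavelength, FWHM and maximum reflectance.
"""

from iriscale import (
    angle_of_max,
    h_sara_stack,
    normalize_min_zero,
    peak_and_fwhm,
    smooth_spectrum,
)
from iriscale.spectra import AngleSeries
from iriscale.synthetic import SyntheticSpec, gen_angle_series

spec = SyntheticSpec(
    taxon="synthetic iridescent wing",
    stack=h_sara_stack(),
    ridge_spacing_nm=723.0,
    angular_envelope=(10.0, 15.0),  # brightest at a 10 degree tilt
    amplitude_pct=30.6,
    noise_sd_pct=0.5,
    seed=42,
)
series = gen_angle_series(spec, angles=range(0, 41, 4))

processed = AngleSeries(
    [normalize_min_zero(smooth_spectrum(s, span=0.3)) for s in series])

angle, max_r = angle_of_max(processed)
best = next(s for s in processed if s.angle_deg == angle)
pk = peak_and_fwhm(best)

print(f"angle of max reflectance : {angle:+.0f} deg (true envelope centre +10)")
print(f"max reflectance          : {max_r:.1f}% of the white standard")
print(f"peak wavelength          : {pk.peak_wavelength_nm:.0f} nm")
if pk.fwhm_missing:
    print("FWHM                     : not measurable (a half-maximum "
          "crossing falls outside 300-700 nm)")
else:
    print(f"FWHM                     : {pk.fwhm_nm:.0f} nm")

# The recovered angle matches the generator's envelope centre to within
# the 4 degree sampling step, and the peak wavelength recovers the
# multilayer's spectral position despite the added measurement noise.
# The two-period stack reflects a band broad enough that its red-side
# half-maximum crossing lies beyond the 700 nm working limit, so the FWHM
# is reported missing rather than extrapolated - the same flagging the
# summary table applies to non-iridescent wings.
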