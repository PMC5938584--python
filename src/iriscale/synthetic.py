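"""Synthetic instrument data for every stage of the pipeline.

Generators emulate the three instruments and the published per-taxon value
set, so all estimators can be exercised end-to-end without any measured
data:

* angle-resolved reflectance series built from the multilayer optics of a
  stack, shaped by a Gaussian angular envelope and Gaussian instrument
  noise (what a fibre-probe spectrometer on a rotation stage records);
* SAXS detector frames with an isotropic Debye-Scherrer-type ring at
  q = 2*pi/spacing over a power-law background, Poisson photon noise and a
  beam-stop mask;
* AFM height maps with parallel ridges at a set spacing, optionally curved
  cross-ridge profiles and saw-tooth along-ridge discontinuities, plus
  seeded surface roughness;
* the transcribed per-taxon summary table used by the reporting stage.

Every generator is a pure function of its parameters and a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import MultilayerStack, h_sara_stack, tmm_reflectance
from .periodicity import DetectorImage, HeightMap
from .spectra import AngleSeries, Spectrum, default_grid
from .stats_report import SummaryRow

# geometry of the SAXS experiment being emulated: 0.1 nm X-rays, 30.98 m
# sample-detector distance
PAPER_GEOMETRY = {
    "xray_wavelength_nm": 0.1,
    "sample_detector_distance_mm": 30980.0,
    "pixel_size_mm": 0.1,
    "shape": (192, 192),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic taxon/wing.

    ``angular_envelope`` is (centre, width) in degrees of the Gaussian
    brightness envelope over tilt angle; ``amplitude_pct`` scales the
    multilayer reflectance so the envelope-centre spectrum peaks near that
    reflectance percentage.
    """

    taxon: str
    stack: MultilayerStack
    ridge_spacing_nm: float
    angular_envelope: tuple[float, float] = (10.0, 15.0)
    amplitude_pct: float = 30.6
    noise_sd_pct: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_spacing_nm <= 0 or self.amplitude_pct <= 0:
            raise ValueError("physical parameters must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise level must be non-negative")


def gen_angle_series(spec: SyntheticSpec,
                     angles: Sequence[float] = tuple(range(0, 41, 4)),
                     grid: np.ndarray | None = None) -> AngleSeries:
    """Synthetic angle-resolved reflectance series for one individual.

    Each angle's spectrum is the stack's unpolarized transfer-matrix
    reflectance at that incidence, scaled by a Gaussian envelope over angle
    and by ``amplitude_pct`` (relative to the envelope-centre maximum),
    with seeded additive Gaussian noise clipped at zero.  The spectral
    peak blue-shifts as the tilt moves away from the envelope centre.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(spec.seed)
    centre, width = spec.angular_envelope
    # normalize amplitude against the unscaled maximum at the envelope centre
    r0 = tmm_reflectance(spec.stack, grid, abs(centre))
    scale = spec.amplitude_pct / (100.0 * np.max(r0))
    out = []
    for ang in angles:
        r = tmm_reflectance(spec.stack, grid, abs(ang))
        env = np.exp(-0.5 * ((ang - centre) / width) ** 2)
        vals = 100.0 * r * scale * env
        if spec.noise_sd_pct > 0:
            vals = vals + rng.normal(0, spec.noise_sd_pct, vals.shape)
        out.append(Spectrum(grid, np.clip(vals, 0, None), taxon=spec.taxon,
                            individual="synthetic", angle_deg=float(ang)))
    return AngleSeries(out)


def gen_gaussian_spectrum(peak_nm: float, fwhm_nm: float, amplitude_pct: float,
                          noise_sd_pct: float = 0.0, seed: int = 0,
                          grid: np.ndarray | None = None,
                          taxon: str = "", individual: str = "") -> Spectrum:
    """A Gaussian reflectance band — the stylized single-angle measurement.

    FWHM converts to sigma via fwhm = 2 sqrt(2 ln 2) sigma.
    """
    if grid is None:
        grid = default_grid()
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = amplitude_pct * np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0, noise_sd_pct, vals.shape), 0, None)
    return Spectrum(grid, vals, taxon=taxon, individual=individual)


def gen_saxs_image(spacing_nm: float, seed: int,
                   geometry: dict | None = None,
                   ring_width_q: float | None = None,
                   ring_intensity: float = 2000.0,
                   background: float = 50.0,
                   beamstop_radius_px: float = 8.0) -> DetectorImage:
    """Synthetic SAXS frame: an isotropic ring at q = 2*pi/spacing.

    The ring is Gaussian in q over a q^-2 power-law background, the whole
    frame is Poisson-sampled at the given seed, and a central beam-stop
    disc is masked out.  Raises when the ring would fall outside the
    detector for the given geometry.
    """
    if spacing_nm <= 0:
        raise ValueError("spacing must be positive")
    geo = dict(PAPER_GEOMETRY)
    if geometry:
        geo.update(geometry)
    ny, nx = geo["shape"]
    center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    q0 = 2 * np.pi / spacing_nm
    if ring_width_q is None:
        ring_width_q = 0.04 * q0

    rows, cols = np.indices((ny, nx))
    r_mm = np.hypot(rows - center[0], cols - center[1]) * geo["pixel_size_mm"]
    two_theta = np.arctan2(r_mm, geo["sample_detector_distance_mm"])
    q = 4 * np.pi / geo["xray_wavelength_nm"] * np.sin(two_theta / 2)
    q_edge = min(
        q[0, int(center[1])], q[-1, int(center[1])],
        q[int(center[0]), 0], q[int(center[0]), -1],
    )
    if q0 + 3 * ring_width_q > q_edge:
        raise ValueError("ring falls outside the detector for this geometry")

    with np.errstate(divide="ignore"):
        bg = background * np.where(q > 0, (q / q0) ** -2.0, 0.0)
    bg = np.minimum(bg, 10 * background)  # cap divergence near the beam stop
    mean = bg + ring_intensity * np.exp(-0.5 * ((q - q0) / ring_width_q) ** 2)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean).astype(float)
    mask = np.hypot(rows - center[0], cols - center[1]) > beamstop_radius_px
    return DetectorImage(
        intensity=counts, beam_center=center,
        pixel_size_mm=geo["pixel_size_mm"],
        sample_detector_distance_mm=geo["sample_detector_distance_mm"],
        xray_wavelength_nm=geo["xray_wavelength_nm"], mask=mask,
    )


def gen_background_only_image(seed: int, geometry: dict | None = None,
                              background: float = 50.0) -> DetectorImage:
    """A featureless frame (power-law background, no ring) for negative tests."""
    img = gen_saxs_image(900.0, seed, geometry, ring_intensity=0.0,
                         background=background)
    return img


def gen_height_map(spacing_nm: float, seed: int, profile: str = "flat",
                   lamellae_sawtooth: bool = False, size_px: int = 512,
                   pitch_nm: float | None = None, ridge_height_nm: float = 150.0,
                   noise_nm: float = 5.0, angle_deg: float = 0.0) -> HeightMap:
    """Synthetic AFM scan: parallel ridges at a set spacing.

    The default field of view is 10 um (pitch = 10000/size_px nm).  The
    ridge cross-section is sinusoidal; ``profile="curved"`` superimposes a
    smooth long-wavelength height modulation across ridges (curved
    lamellae), and ``lamellae_sawtooth`` adds along-ridge saw-tooth
    discontinuities.  ``angle_deg`` rotates the ridge direction in-plane.
    Raises when the field of view holds fewer than 4 ridge periods.
    """
    if pitch_nm is None:
        pitch_nm = 10000.0 / size_px
    if size_px * pitch_nm < 4 * spacing_nm:
        raise ValueError("map must span at least 4 ridge periods")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size_px, 0:size_px] * pitch_nm
    th = np.radians(angle_deg)
    u = xx * np.cos(th) + yy * np.sin(th)   # across-ridge coordinate
    v = -xx * np.sin(th) + yy * np.cos(th)  # along-ridge coordinate
    z = 0.5 * ridge_height_nm * np.cos(2 * np.pi * u / spacing_nm)
    if profile == "curved":
        z = z + 40.0 * np.sin(2 * np.pi * u / (6.3 * spacing_nm))
    elif profile != "flat":
        raise ValueError("profile must be 'flat' or 'curved'")
    if lamellae_sawtooth:
        saw_period = 1200.0
        z = z + 20.0 * ((v % saw_period) / saw_period - 0.5)
    if noise_nm > 0:
        z = z + rng.normal(0, noise_nm, z.shape)
    return HeightMap(z, pitch_nm)


# ---------------------------------------------------------------------------
# Published per-taxon summary values (reporting-stage fixture)
# ---------------------------------------------------------------------------

def table1_fixture() -> list[SummaryRow]:
    """The published per-taxon summary table, transcribed verbatim.

    Eight taxa; AFM spacing is a single image-average (no s.d.), other
    descriptors are means of four individuals +/- s.d. (one individual for
    *H. sara* Panama).  Missing modalities are None; "~700" boundary peaks
    carry ``peak_at_boundary=True`` with FWHM and angle missing.
    """
    def row(taxon, afm, saxs, saxs_sd, peak, peak_sd, fwhm, fwhm_sd,
            ang, ang_sd, refl, refl_sd, boundary=False):
        return SummaryRow(
            taxon=taxon, ridge_spacing_afm_nm=afm,
            ridge_spacing_saxs_nm=saxs, ridge_spacing_saxs_sd=saxs_sd,
            peak_wavelength_nm=peak, peak_wavelength_sd=peak_sd,
            fwhm_nm=fwhm, fwhm_sd=fwhm_sd,
            angle_of_max_deg=ang, angle_of_max_sd=ang_sd,
            max_reflectance_pct=refl, max_reflectance_sd=refl_sd,
            peak_at_boundary=boundary,
        )

    return [
        row("H. erato cyrbia", 887, 812, 28, 369, 8, 177, 12,
            11.8, 4.9, 19.4, 9.3),
        row("H. erato demophoon", 1149, 1063, 39, 700, None, None, None,
            None, None, 2.4, 1.4, boundary=True),
        row("H. sara (Ecuador)", 723, 742, 28, 497, 7, 191, 5,
            10.0, 7.2, 30.6, 10.1),
        row("H. sara (Panama)", None, None, None, 443, 3, 274, 2,
            3.5, 0.7, 15.9, 2.1),
        row("H. eleuchia", 1159, 889, 73, 455, 12, 172, 1,
            6.0, 3.5, 14.4, 5.3),
        row("H. cydno", 1143, 929, 58, 390, 2, 192, 20,
            6.7, 3.0, 3.4, 1.1),
        row("H. melpomene cythera", 1242, 823, 22, 362, 10, 180, 9,
            16.7, 4.6, 6.4, 2.4),
        row("H. melpomene rosina", 1253, 1025, 82, 700, None, None, None,
            None, None, 1.9, 0.7, boundary=True),
    ]


def gen_comimic_groups(n_per_group: int = 4, period_delta_nm: float = 8.0,
                       noise_sd_pct: float = 0.5, seed: int = 0
                       ) -> tuple[list[Spectrum], list[Spectrum]]:
    """Two synthetic co-mimic wing groups differing by a small period shift.

    Group A uses the measured iridescent-ridge stack; group B's unit cell
    is thicker by ``period_delta_nm`` (split across air and chitin), which
    shifts its reflectance peak by roughly twice that amount.  Each group
    holds ``n_per_group`` individuals with independent seeded noise — the
    desk-scale stand-in for comparing co-mimetic wings.
    """
    grid = default_grid()
    stack_a = h_sara_stack()
    stack_b = h_sara_stack(d_air=119.0 + period_delta_nm / 2.0,
                           d_chitin=85.0 + period_delta_nm / 2.0)
    rng = np.random.default_rng(seed)
    groups: tuple[list[Spectrum], list[Spectrum]] = ([], [])
    for gi, stack in enumerate((stack_a, stack_b)):
        base = 100.0 * tmm_reflectance(stack, grid, 0.0)
        base = base * (30.0 / base.max())
        for k in range(n_per_group):
            vals = base + rng.normal(0, noise_sd_pct, base.shape)
            groups[gi].append(Spectrum(
                grid, np.clip(vals, 1e-3, None),
                taxon=f"mimic_{'ab'[gi]}", individual=f"{'ab'[gi]}{k + 1}"))
    return groups
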