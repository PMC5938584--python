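"""Ridge-spacing estimation from SAXS detector images and AFM height maps.

The longitudinal ridges of a wing scale form a quasi-periodic grating with
spacing of order 1 um.  Two independent instruments see it:

* transmission small-angle X-ray scattering: the grating produces a
  Debye-Scherrer-type ring at momentum transfer q = 2*pi/spacing on the 2-D
  detector.  The image is radially integrated to I(q), a power-law
  background is removed, and the peak position gives the spacing.
* atomic-force microscopy: the height map is de-trended, Hann-windowed and
  Fourier transformed; the azimuthally integrated power spectrum peaks at
  spatial frequency 1/spacing.

Geometry follows the small-angle convention q = (4*pi/lambda) * sin(theta)
with 2*theta the scattering angle, so q in nm^-1 converts to real-space
spacing d = 2*pi/q in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# defaults bracketing ridge spacings of 500-1500 nm
DEFAULT_Q_WINDOW = (2 * np.pi / 1500.0, 2 * np.pi / 500.0)


class NoPeakError(ValueError):
    """Raised when no spacing peak is found in a profile or power spectrum."""


@dataclass
class DetectorImage:
    """A corrected 2-D SAXS detector frame with beam geometry.

    ``beam_center`` is (row, col) in 0-based, possibly fractional pixels.
    ``mask`` is True where pixels are valid (beam stop and edges False).
    """

    intensity: np.ndarray
    beam_center: tuple[float, float]
    pixel_size_mm: float
    sample_detector_distance_mm: float
    xray_wavelength_nm: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.sample_detector_distance_mm <= 0 or self.xray_wavelength_nm <= 0:
            raise ValueError("distance and wavelength must be positive")
        if self.mask is None:
            self.mask = np.ones(self.intensity.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ValueError("mask shape must match intensity shape")


@dataclass
class ScatteringProfile:
    """Radially averaged intensity I(q); q strictly increasing, in nm^-1."""

    q_nm_inv: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.q_nm_inv = np.asarray(self.q_nm_inv, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q_nm_inv.size == 0:
            raise ValueError("empty scattering profile")
        if np.any(np.diff(self.q_nm_inv) <= 0):
            raise ValueError("q values must be strictly increasing")
        if np.any(self.q_nm_inv <= 0):
            raise ValueError("q values must be positive")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class HeightMap:
    """AFM topography: heights in nm on a square-pixel grid."""

    height_nm: np.ndarray
    pixel_pitch_nm: float

    def __post_init__(self) -> None:
        self.height_nm = np.asarray(self.height_nm, dtype=float)
        if self.height_nm.ndim != 2:
            raise ValueError("height map must be 2-D")
        if not np.all(np.isfinite(self.height_nm)):
            raise ValueError("heights must be finite")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")


def q_of_pixel(img: DetectorImage, pixel: tuple[float, float]) -> float:
    """Momentum transfer q (nm^-1) of a detector pixel.

    r = distance from beam centre in mm; 2*theta = atan(r / D);
    q = (4*pi/lambda) * sin(theta).
    """
    dr = pixel[0] - img.beam_center[0]
    dc = pixel[1] - img.beam_center[1]
    r_mm = np.hypot(dr, dc) * img.pixel_size_mm
    two_theta = np.arctan2(r_mm, img.sample_detector_distance_mm)
    return float(4 * np.pi / img.xray_wavelength_nm * np.sin(two_theta / 2))


def _q_map(img: DetectorImage) -> np.ndarray:
    rows, cols = np.indices(img.intensity.shape)
    r_mm = np.hypot(rows - img.beam_center[0],
                    cols - img.beam_center[1]) * img.pixel_size_mm
    two_theta = np.arctan2(r_mm, img.sample_detector_distance_mm)
    return 4 * np.pi / img.xray_wavelength_nm * np.sin(two_theta / 2)


def radial_integrate(img: DetectorImage, q_bins: int = 200) -> ScatteringProfile:
    """Azimuthal (radial) average of masked intensity into q bins.

    Bin value is the mean intensity of valid pixels falling in the bin;
    bins with no valid pixels (and the q = 0 bin) are dropped.
    """
    q = _q_map(img)[img.mask]
    inten = img.intensity[img.mask]
    if q.size == 0:
        raise ValueError("fully masked image: nothing to integrate")
    edges = np.linspace(0, q.max(), q_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, q_bins - 1)
    counts = np.bincount(idx, minlength=q_bins)
    sums = np.bincount(idx, weights=inten, minlength=q_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = (counts > 0) & (centers > 0)
    if not np.any(keep):
        raise ValueError("no populated q bins")
    return ScatteringProfile(centers[keep], sums[keep] / counts[keep])


def _power_law_background(q: np.ndarray, inten: np.ndarray,
                          window: tuple[float, float]) -> np.ndarray:
    """Fit I = A * q^-m on the regions flanking the peak window."""
    flank = ((q < window[0]) | (q > window[1])) & (inten > 0)
    if flank.sum() < 2:
        return np.zeros_like(q)
    coef = np.polyfit(np.log(q[flank]), np.log(inten[flank]), 1)
    return np.exp(np.polyval(coef, np.log(q)))


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to x[i]."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1)
    return float(-b / (2 * a))


def ridge_spacing_from_profile(profile: ScatteringProfile,
                               q_window: tuple[float, float] = DEFAULT_Q_WINDOW
                               ) -> float:
    """Ridge spacing (nm) from the structure peak of a 1-D SAXS profile.

    A single power-law background fitted on the flanking regions is
    subtracted, the maximum inside the window is located with 3-point
    parabolic refinement, and d = 2*pi/q_peak is returned.

    Raises :class:`NoPeakError` when the window holds no local maximum
    above background.
    """
    q, inten = profile.q_nm_inv, profile.intensity
    sel = (q >= q_window[0]) & (q <= q_window[1])
    if sel.sum() < 3:
        raise NoPeakError("q window holds fewer than 3 profile points")
    bg = _power_law_background(q, inten, q_window)
    resid = inten - bg
    flank = ~sel
    flank_rms = float(np.sqrt(np.mean(resid[flank] ** 2))) if flank.any() else 0.0
    qw, rw = q[sel], resid[sel]
    i = int(np.argmax(rw))
    # require an interior maximum clearly above the background-fit residual
    if not 0 < i < len(qw) - 1 or rw[i] <= max(3 * flank_rms, 0.0):
        raise NoPeakError("no peak above background inside the q window")
    q_peak = _parabolic_refine(qw, rw, i)
    return float(2 * np.pi / q_peak)


def afm_ridge_spacing(height_map: HeightMap,
                      spacing_window_nm: tuple[float, float] = (500.0, 1500.0)
                      ) -> float:
    """Image-averaged ridge spacing (nm) from the integrated Fourier transform.

    The map is de-trended by removing the best-fit plane, Hann-windowed to
    suppress edge leakage, and its 2-D power spectrum is azimuthally
    integrated to power vs radial spatial frequency.  The dominant non-DC
    peak inside the expected spacing window gives spacing = 1/frequency.
    Rotation of the ridge pattern in the image plane does not change the
    result.
    """
    z = height_map.height_nm
    ny, nx = z.shape
    # de-trend: remove best-fit plane
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(z.size), xx.ravel(), yy.ravel()])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    zd = z - (A @ coef).reshape(z.shape)
    if np.allclose(zd, 0):
        raise NoPeakError("featureless height map")
    win = np.outer(np.hanning(ny), np.hanning(nx))
    power = np.abs(np.fft.fftshift(np.fft.fft2(zd * win))) ** 2

    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=height_map.pixel_pitch_nm))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=height_map.pixel_pitch_nm))
    fr = np.hypot.outer(fy, fx)

    df = 1.0 / (max(ny, nx) * height_map.pixel_pitch_nm)
    nbins = int(fr.max() / df) + 1
    idx = np.minimum(np.round(fr / df).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    centers = np.arange(nbins) * df
    valid = counts > 0
    prof = np.where(valid, sums / np.maximum(counts, 1), 0.0)

    lo, hi = 1.0 / spacing_window_nm[1], 1.0 / spacing_window_nm[0]
    sel = valid & (centers >= lo) & (centers <= hi) & (centers > 0)
    if not np.any(sel):
        raise NoPeakError("no spatial-frequency bins inside the spacing window")
    cand = np.flatnonzero(sel)
    i = int(cand[np.argmax(prof[cand])])
    # guard against broadband noise: the peak bin must dominate the window
    if prof[i] <= 0 or (len(cand) > 2 and prof[i] < 2.0 * prof[cand].mean()):
        raise NoPeakError("no dominant peak at ridge spatial frequencies")
    # refine by the power-weighted centroid of frequencies near the peak
    # (the Hann-window side lobes spread symmetrically about the true line)
    near = np.abs(fr - centers[i]) <= 2 * df
    f_peak = float((power[near] * fr[near]).sum() / power[near].sum())
    if f_peak <= 0:
        raise NoPeakError("degenerate power spectrum")
    return float(1.0 / f_peak)


# ---------------------------------------------------------------------------
# Grid I/O: plain-text arrays with a JSON geometry sidecar
# ---------------------------------------------------------------------------

def write_detector_image(img: DetectorImage, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, img.intensity, fmt="%.6g")
    np.savetxt(path.with_suffix(".mask.txt"), img.mask.astype(int), fmt="%d")
    sidecar = {
        "distance_mm": img.sample_detector_distance_mm,
        "wavelength_nm": img.xray_wavelength_nm,
        "pixel_size_mm": img.pixel_size_mm,
        "beam_center": list(img.beam_center),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_detector_image(path: str | Path) -> DetectorImage:
    path = Path(path)
    inten = np.loadtxt(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask_path = path.with_suffix(".mask.txt")
    mask = np.loadtxt(mask_path).astype(bool) if mask_path.exists() else None
    return DetectorImage(
        intensity=inten,
        beam_center=tuple(meta["beam_center"]),
        pixel_size_mm=meta["pixel_size_mm"],
        sample_detector_distance_mm=meta["distance_mm"],
        xray_wavelength_nm=meta["wavelength_nm"],
        mask=mask,
    )


def write_height_map(hm: HeightMap, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, hm.height_nm, fmt="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps({"pixel_pitch_nm": hm.pixel_pitch_nm}))


def read_height_map(path: str | Path) -> HeightMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return HeightMap(np.loadtxt(path), meta["pixel_pitch_nm"])
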