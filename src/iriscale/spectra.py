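"""Angle-resolved reflectance spectra: containers, processing and summaries.

The measurement currency of the pipeline is a reflectance spectrum expressed
in percent of a diffuse white standard on a wavelength grid in nm.  A series
of such spectra taken at different tilt angles of the same wing patch is an
:class:`AngleSeries`.  Processing follows the standard spectrometry chain:
resample to a common grid, smooth with a local-regression (LOESS) filter,
clamp negatives to zero, shift the minimum to zero, average replicates, and
extract peak wavelength / FWHM / maximum reflectance within the working
range visible to birds and butterflies (300-700 nm).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WORKING_RANGE = (300.0, 700.0)
DEFAULT_STEP_NM = 1.0


@dataclass(frozen=True)
class Spectrum:
    """A sampled reflectance spectrum with acquisition metadata.

    Parameters
    ----------
    wavelength_nm:
        Strictly increasing wavelength grid in nm, at least two points.
    reflectance_pct:
        Reflectance in percent of a diffuse white standard; finite values.
    taxon, wing, individual:
        Identity of the measured specimen (wing is ``"fore"`` or ``"hind"``).
    angle_deg:
        Signed tilt angle of the wing relative to normal incidence.
    """

    wavelength_nm: np.ndarray
    reflectance_pct: np.ndarray
    taxon: str = ""
    wing: str = "fore"
    individual: str = ""
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        r = np.asarray(self.reflectance_pct, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if r.shape != wl.shape:
            raise ValueError("reflectance and wavelength shapes differ")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance values must be finite")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "reflectance_pct", r)

    def with_values(self, reflectance_pct: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new reflectance values, same metadata."""
        return replace(self, reflectance_pct=np.asarray(reflectance_pct, float))


@dataclass
class AngleSeries:
    """Spectra of one taxon/wing/individual, one per tilt angle.

    Angles must be unique and all member spectra must share one grid.
    """

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            angles = [s.angle_deg for s in self.spectra]
            if len(set(angles)) != len(angles):
                raise ValueError("angles in a series must be unique")
            grid = self.spectra[0].wavelength_nm
            for s in self.spectra[1:]:
                if not np.array_equal(s.wavelength_nm, grid):
                    raise ValueError("all spectra in a series must share a grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle_deg for s in self.spectra])


def default_grid(lo: float = WORKING_RANGE[0], hi: float = WORKING_RANGE[1],
                 step: float = DEFAULT_STEP_NM) -> np.ndarray:
    """Inclusive wavelength grid in nm at the given step (default 1 nm)."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def resample_to_grid(spec: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid inside its range."""
    grid = np.asarray(grid, dtype=float)
    wl = spec.wavelength_nm
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] outside measured "
            f"range [{wl[0]}, {wl[-1]}]"
        )
    vals = np.interp(grid, wl, spec.reflectance_pct)
    return replace(spec, wavelength_nm=grid, reflectance_pct=vals)


def _loess(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local quadratic regression with tricube weights.

    ``span`` is the fraction of points in each local window.  Evaluated at
    every input point; exact on globally quadratic data within a window.
    """
    n = x.size
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValueError(f"span {span} gives a window of {k} < 3 points")
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        xi = x[idx] - x[i]
        X = np.column_stack([np.ones(k), xi, xi * xi])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def smooth_spectrum(spec: Spectrum, span: float = 0.3) -> Spectrum:
    """LOESS-smooth a spectrum and clamp negative smoothed values to zero.

    ``span`` is the fraction of points in the local window (0 < span <= 1).
    The negative clamp is applied after smoothing ("fix negatives to zero").
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    sm = _loess(spec.wavelength_nm, spec.reflectance_pct, span)
    return spec.with_values(np.maximum(sm, 0.0))


def normalize_min_zero(spec: Spectrum,
                       window: tuple[float, float] = WORKING_RANGE) -> Spectrum:
    """Subtract the minimum reflectance over the working range.

    The output minimum within the window is exactly zero; idempotent.
    """
    wl = spec.wavelength_nm
    sel = (wl >= window[0]) & (wl <= window[1])
    if not np.any(sel):
        sel = np.ones_like(wl, bool)
    return spec.with_values(spec.reflectance_pct - spec.reflectance_pct[sel].min())


def average_spectra(specs: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing a common grid."""
    if not specs:
        raise ValueError("cannot average an empty list of spectra")
    grid = specs[0].wavelength_nm
    for s in specs[1:]:
        if not np.array_equal(s.wavelength_nm, grid):
            raise ValueError("spectra must share a common grid; resample first")
    mean = np.mean([s.reflectance_pct for s in specs], axis=0)
    return specs[0].with_values(mean)


@dataclass(frozen=True)
class PeakSummary:
    peak_wavelength_nm: float
    fwhm_nm: float | None
    max_reflectance_pct: float
    peak_at_boundary: bool
    fwhm_missing: bool


def peak_and_fwhm(spec: Spectrum,
                  window: tuple[float, float] = WORKING_RANGE) -> PeakSummary:
    """Peak wavelength, FWHM and maximum reflectance within a window.

    The peak is the argmax inside the window.  FWHM comes from linear
    interpolation of the two half-maximum crossings flanking the peak; if a
    crossing falls outside the window the FWHM is reported missing.  A peak
    on the window boundary (monotone spectrum) is flagged: non-iridescent
    wings whose reflectance still rises at 700 nm report a "~700" peak.
    """
    wl = spec.wavelength_nm
    sel = (wl >= window[0]) & (wl <= window[1])
    if not np.any(sel):
        raise ValueError("spectrum does not cover the requested window")
    w = wl[sel]
    r = spec.reflectance_pct[sel]
    i = int(np.argmax(r))
    peak_wl = float(w[i])
    peak_r = float(r[i])
    boundary = i == 0 or i == len(w) - 1

    half = peak_r / 2.0

    def _cross(side: str) -> float | None:
        if side == "left":
            rng = range(i, 0, -1)
            step = -1
        else:
            rng = range(i, len(w) - 1)
            step = 1
        for j in rng:
            a, b = r[j], r[j + step]
            if (a - half) * (b - half) <= 0 and a != b:
                wa, wb = w[j], w[j + step]
                return float(wa + (half - a) * (wb - wa) / (b - a))
        return None

    left = _cross("left")
    right = _cross("right")
    missing = left is None or right is None
    fwhm = None if missing else right - left
    return PeakSummary(peak_wl, fwhm, peak_r, boundary, missing)


def angle_of_max(series: AngleSeries, refine: bool = False,
                 window: tuple[float, float] = WORKING_RANGE
                 ) -> tuple[float, float]:
    """Angle whose spectrum attains the global maximum reflectance.

    Ties break toward the smaller absolute angle.  With ``refine`` a
    quadratic is fitted through the three angles bracketing the maximum
    (off by default).
    """
    if len(series) < 2:
        raise ValueError("angle series needs at least two angles")
    maxima = []
    for s in series:
        sel = (s.wavelength_nm >= window[0]) & (s.wavelength_nm <= window[1])
        maxima.append(float(s.reflectance_pct[sel].max()))
    maxima = np.array(maxima)
    angles = series.angles
    best = maxima.max()
    tied = np.flatnonzero(maxima == best)
    i = tied[np.argmin(np.abs(angles[tied]))]
    angle = float(angles[i])
    if refine:
        order = np.argsort(angles)
        pos = int(np.flatnonzero(order == i)[0])
        if 0 < pos < len(order) - 1:
            tri = order[pos - 1:pos + 2]
            a, m = angles[tri], maxima[tri]
            denom = (a[0] - a[1]) * (a[0] - a[2]) * (a[1] - a[2])
            if denom != 0:
                A = (a[2] * (m[1] - m[0]) + a[1] * (m[0] - m[2])
                     + a[0] * (m[2] - m[1])) / denom
                B = (a[2] ** 2 * (m[0] - m[1]) + a[1] ** 2 * (m[2] - m[0])
                     + a[0] ** 2 * (m[1] - m[2])) / denom
                if A < 0:
                    angle = float(-B / (2 * A))
    return angle, float(best)


# ---------------------------------------------------------------------------
# File I/O: two-column CSV per angle, metadata in the filename or a sidecar
# ---------------------------------------------------------------------------

_FNAME_RE = re.compile(
    r"^(?P<taxon>[^_]+)_(?P<wing>fore|hind)_(?P<individual>[^_]+)"
    r"_(?P<angle>[-+]?\d+(?:\.\d+)?)deg\.csv$"
)

CSV_HEADER = "wavelength_nm,reflectance_pct"


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    """Write one spectrum as a two-column CSV with a standard header."""
    path = Path(path)
    data = np.column_stack([spec.wavelength_nm, spec.reflectance_pct])
    np.savetxt(path, data, delimiter=",", header=CSV_HEADER, comments="",
               fmt="%.6g")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column CSV spectrum.

    Metadata is parsed from a ``taxon_wing_individual_<angle>deg.csv``
    filename when it matches; a JSON sidecar ``<name>.json`` with any of
    ``taxon``, ``wing``, ``individual``, ``angle_deg`` overrides it.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = {"taxon": "", "wing": "fore", "individual": "", "angle_deg": 0.0}
    m = _FNAME_RE.match(path.name)
    if m:
        meta.update(taxon=m["taxon"], wing=m["wing"],
                    individual=m["individual"], angle_deg=float(m["angle"]))
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Spectrum(data[:, 0], data[:, 1], **meta)


def process_spectrum(spec: Spectrum, span: float = 0.3,
                     grid: np.ndarray | None = None) -> Spectrum:
    """Standard chain: resample -> LOESS smooth -> min-zero normalize."""
    if grid is None:
        lo = max(WORKING_RANGE[0], spec.wavelength_nm[0])
        hi = min(WORKING_RANGE[1], spec.wavelength_nm[-1])
        grid = default_grid(np.ceil(lo), np.floor(hi))
    out = resample_to_grid(spec, grid)
    out = smooth_spectrum(out, span=span)
    return normalize_min_zero(out)


def summarize_series(series: AngleSeries) -> dict:
    """Per-individual summary: angle of max, then peak/FWHM at that angle."""
    angle, max_r = angle_of_max(series)
    best = next(s for s in series if s.angle_deg == angle)
    pk = peak_and_fwhm(best)
    return {
        "taxon": best.taxon,
        "wing": best.wing,
        "individual": best.individual,
        "angle_of_max_deg": angle,
        "max_reflectance_pct": max_r,
        "peak_wavelength_nm": pk.peak_wavelength_nm,
        "fwhm_nm": pk.fwhm_nm,
        "peak_at_boundary": pk.peak_at_boundary,
    }
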