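"""Multilayer interference model of the ridge lamellae.

The iridescent ridges of *Heliconius* wing scales carry stacked chitin
lamellae separated by air, a one-dimensional photonic multilayer.  Two
routes to its reflectance are provided:

* the first-order constructive-interference (Bragg) condition
  ``lambda_1 = 2 * sum_i d_i * sqrt(n_i^2 - sin^2 theta)``, which at normal
  incidence reduces to twice the optical path of the unit cell, and
* the exact characteristic (transfer) matrix method for the finite lossless
  stack between ambient and substrate, for s, p or unpolarized light.

Indices are wavelength-independent and real (non-absorbing model): the
quantitative claim being modelled — a ~500 nm reflectance peak from
119 nm air / 85 nm chitin layers — is a lossless interference calculation.
An optional imaginary index hook exists for scalar attenuation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import Spectrum

N_CHITIN = 1.56
N_AIR = 1.0


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab: refractive index (>= 1, real) and thickness in nm."""

    refractive_index: float
    thickness_nm: float
    extinction: float = 0.0  # imaginary index hook, default lossless

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_nm) or self.thickness_nm <= 0:
            raise ValueError("layer thickness must be positive and finite")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1 (non-absorbing model)")

    @property
    def n_complex(self) -> complex:
        return self.refractive_index + 1j * self.extinction


@dataclass(frozen=True)
class MultilayerStack:
    """A periodic multilayer: a unit cell of layers repeated ``repeats`` times.

    Ambient defaults to air above the scale; the substrate defaults to
    chitin, the bulk of the ridge beneath the lamellae.
    """

    unit_cell: tuple[Layer, ...]
    repeats: int = 2
    ambient_index: float = N_AIR
    substrate_index: float = N_CHITIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_cell", tuple(self.unit_cell))
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def layers(self) -> tuple[Layer, ...]:
        return self.unit_cell * self.repeats


def h_sara_stack(d_air: float = 119.0, d_chitin: float = 85.0,
                 n_chitin: float = N_CHITIN, repeats: int = 2) -> MultilayerStack:
    """The measured *H. sara* ridge multilayer: air over chitin, two periods."""
    return MultilayerStack(
        unit_cell=(Layer(N_AIR, d_air), Layer(n_chitin, d_chitin)),
        repeats=repeats,
    )


def stack_period(stack: MultilayerStack) -> float:
    """Period of the stack: the sum of unit-cell thicknesses in nm."""
    return float(sum(l.thickness_nm for l in stack.unit_cell))


def effective_index(stack: MultilayerStack) -> float:
    """Thickness-weighted arithmetic mean index of the unit cell.

    n_eff = sum(n_i d_i) / sum(d_i).
    """
    d = np.array([l.thickness_nm for l in stack.unit_cell])
    n = np.array([l.refractive_index for l in stack.unit_cell])
    return float((n * d).sum() / d.sum())


def bragg_peak_wavelength(stack: MultilayerStack, theta_deg: float = 0.0) -> float:
    """First-order constructive-interference wavelength of the unit cell in nm.

    lambda_1 = 2 * sum_i d_i sqrt(n_i^2 - sin^2 theta); at normal incidence
    this is twice the optical thickness of the period.  Strictly decreasing
    in theta — the blue-shift that makes the colour iridescent.
    """
    if not 0 <= theta_deg < 90:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    s2 = np.sin(np.radians(theta_deg)) ** 2
    return float(sum(
        2.0 * l.thickness_nm * np.sqrt(l.refractive_index ** 2 - s2)
        for l in stack.unit_cell
    ))


def _admittances(n: np.ndarray, n0: float, theta0_rad: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """cos(theta) in each medium (Snell) and the s/p optical admittances."""
    sin_t = n0 * np.sin(theta0_rad) / n
    cos_t = np.sqrt(1 - sin_t ** 2 + 0j)
    eta_s = n * cos_t
    eta_p = n / cos_t
    return cos_t, eta_s, eta_p


def tmm_reflectance(stack: MultilayerStack, wavelength_nm, theta_deg: float = 0.0,
                    polarization: str = "unpolarized"):
    """Reflectance of the finite stack by the characteristic-matrix method.

    Returns a fraction in [0, 1]; scalar in, scalar out.  ``polarization``
    is ``"s"``, ``"p"`` or ``"unpolarized"`` (the mean of s and p).
    """
    if polarization not in ("s", "p", "unpolarized"):
        raise ValueError("polarization must be 's', 'p' or 'unpolarized'")
    if not 0 <= theta_deg < 90:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    theta0 = np.radians(theta_deg)
    layers = stack.layers
    n_all = np.array([stack.ambient_index]
                     + [l.n_complex for l in layers]
                     + [stack.substrate_index], dtype=complex)
    d = np.array([l.thickness_nm for l in layers])
    cos_t, eta_s, eta_p = _admittances(n_all, stack.ambient_index, theta0)

    out = {}
    for pol in ("s", "p") if polarization == "unpolarized" else (polarization,):
        eta = eta_s if pol == "s" else eta_p
        # characteristic matrix product, vectorized over wavelength
        B = np.ones(lam.size, dtype=complex)
        C = np.full(lam.size, eta[-1], dtype=complex)
        for j in range(len(layers), 0, -1):
            delta = 2 * np.pi * n_all[j] * cos_t[j] * d[j - 1] / lam
            cd, sd = np.cos(delta), np.sin(delta)
            Bn = cd * B + 1j * sd / eta[j] * C
            Cn = 1j * eta[j] * sd * B + cd * C
            B, C = Bn, Cn
        r = (eta[0] * B - C) / (eta[0] * B + C)
        out[pol] = np.abs(r) ** 2
    R = np.mean(list(out.values()), axis=0)
    return float(R[0]) if np.isscalar(wavelength_nm) else R


def reflectance_spectrum(stack: MultilayerStack, grid: Sequence[float],
                         theta_deg: float = 0.0,
                         polarization: str = "unpolarized",
                         taxon: str = "", wing: str = "fore",
                         individual: str = "") -> Spectrum:
    """TMM reflectance over a wavelength grid, as a percent Spectrum."""
    grid = np.asarray(grid, dtype=float)
    R = tmm_reflectance(stack, grid, theta_deg, polarization)
    return Spectrum(grid, 100.0 * np.asarray(R), taxon=taxon, wing=wing,
                    individual=individual, angle_deg=theta_deg)


# ---------------------------------------------------------------------------
# JSON serialization of stack descriptions
# ---------------------------------------------------------------------------

def stack_to_json(stack: MultilayerStack) -> str:
    return json.dumps({
        "ambient": stack.ambient_index,
        "substrate": stack.substrate_index,
        "unit_cell": [{"n": l.refractive_index, "d_nm": l.thickness_nm}
                      for l in stack.unit_cell],
        "repeats": stack.repeats,
    })


def stack_from_json(text_or_path: str | Path) -> MultilayerStack:
    """Load a stack from a JSON string or a path to a JSON file."""
    p = Path(str(text_or_path))
    raw = p.read_text() if p.exists() else str(text_or_path)
    obj = json.loads(raw)
    return MultilayerStack(
        unit_cell=tuple(Layer(c["n"], c["d_nm"]) for c in obj["unit_cell"]),
        repeats=int(obj.get("repeats", 1)),
        ambient_index=float(obj.get("ambient", N_AIR)),
        substrate_index=float(obj.get("substrate", N_CHITIN)),
    )
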