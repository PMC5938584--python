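"""Receptor-noise-limited visual modelling for birds and *Heliconius*.

The question the model answers: how different do two wing reflectances look
to a given observer?  The chain is

1. receptor spectral sensitivities, built from an A1 visual-pigment
   template (Govardovskii-type alpha band plus beta band) at each
   receptor's peak wavelength;
2. quantum catches Q_i = integral of reflectance x sensitivity x
   illuminant x ocular-media transmission over 300-700 nm, optionally
   von Kries normalized to the catch of a perfect white reflector under
   the adapting illuminant;
3. chromatic coordinates in the Maxwell triangle (trichromats) or the
   colour tetrahedron (tetrachromats), centroid = achromatic;
4. discriminability in just-noticeable differences (JND) under the
   receptor-noise-limited model with log-coded signals
   ``delta_f_i = ln(Q_a,i / Q_b,i)`` and noise ``e_i = w * sqrt(eta_L /
   eta_i)``, the long-wavelength receptor (abundance 1) carrying the
   stated Weber fraction w.  Achromatic JND uses the L receptor alone:
   ``|ln(Q_a,L / Q_b,L)| / w``.

Five built-in observers: the average avian violet-sensitive (VS) system
and the four *Heliconius* photoreceptor complements (tetrachromatic
types I and III, trichromatic types II and IV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .spectra import Spectrum, WORKING_RANGE, default_grid

GRID = default_grid()  # 300..700 nm inclusive, 1 nm


# ---------------------------------------------------------------------------
# Visual-pigment template
# ---------------------------------------------------------------------------

def pigment_sensitivity(lambda_max: float, grid: np.ndarray = GRID) -> np.ndarray:
    """A1 visual-pigment absorbance template, unit peak.

    Alpha band: S(x) = 1 / (exp(69.7 (a - x)) + exp(28 (0.922 - x))
    + exp(-14.9 (1.104 - x)) + 0.674) with x = lambda_max / lambda and
    a = 0.8795 + 0.0459 exp(-(lambda_max - 300)^2 / 11940).
    Beta band: 0.26 exp(-((lambda - lambda_mb) / b)^2) with
    lambda_mb = 189 + 0.315 lambda_max and b = -40.5 + 0.195 lambda_max.
    The sum is renormalized to unit peak on the grid.
    """
    if not 300 <= lambda_max <= 650:
        raise ValueError("lambda_max must lie in [300, 650] nm")
    lam = np.asarray(grid, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-(lambda_max - 300.0) ** 2 / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lam_mb = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-((lam - lam_mb) / b) ** 2)
    s = alpha + beta
    return s / s.max()


# ---------------------------------------------------------------------------
# Illuminants and ocular media
# ---------------------------------------------------------------------------

# CIE standard illuminant D65, relative spectral power, 300-700 nm at 5 nm.
_D65_WL = np.arange(300, 701, 5, dtype=float)
_D65_SPD = np.array([
    0.0341, 1.6643, 3.2945, 11.7652, 20.2360, 28.6447, 37.0535, 38.5011,
    39.9488, 42.4302, 44.9117, 45.7750, 46.6383, 49.3637, 52.0891, 51.0323,
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204, 91.4860, 92.4589,
    93.4318, 90.0570, 86.6823, 95.7736, 104.8650, 110.9360, 117.0080,
    117.4100, 117.8120, 116.3360, 114.8610, 115.3920, 115.9230, 112.3670,
    108.8110, 109.0820, 109.3540, 108.5780, 107.8020, 106.2960, 104.7900,
    106.2390, 107.6890, 106.0470, 104.4050, 104.2250, 104.0460, 102.0230,
    100.0000, 98.1671, 96.3342, 96.0611, 95.7880, 92.2368, 88.6856, 89.3459,
    90.0062, 89.8026, 89.5991, 88.6489, 87.6987, 85.4936, 83.2886, 83.4939,
    83.6992, 81.8630, 80.0268, 80.1207, 80.2146, 81.2462, 82.2778, 80.2810,
    78.2842, 74.0027, 69.7213, 70.6652, 71.6091,
])


@dataclass(frozen=True)
class Illuminant:
    """An irradiance spectrum on 300-700 nm, arbitrary units."""

    name: str
    irradiance: np.ndarray  # on GRID

    def __post_init__(self) -> None:
        irr = np.asarray(self.irradiance, dtype=float)
        if irr.shape != GRID.shape:
            raise ValueError("illuminant must be tabulated on the 1 nm grid")
        if np.any(irr < 0):
            raise ValueError("irradiance must be non-negative")
        object.__setattr__(self, "irradiance", irr)


def d65() -> Illuminant:
    """CIE D65 daylight restricted to 300-700 nm, interpolated to 1 nm."""
    return Illuminant("D65", np.interp(GRID, _D65_WL, _D65_SPD))


def forest_shade() -> Illuminant:
    """Canopy-filtered daylight: D65 attenuated by a green-transmitting filter.

    The filter is a smooth Gaussian transmission band centred at 550 nm
    (width 90 nm) over a 10% broadband floor, which reproduces the defining
    features of light under a closed canopy: strongly UV- and blue-poor,
    with a pronounced green-yellow maximum.  A stylized construction, not a
    field measurement.
    """
    t = 0.10 + 0.90 * np.exp(-((GRID - 550.0) / 90.0) ** 2)
    return Illuminant("forestshade", np.interp(GRID, _D65_WL, _D65_SPD) * t)


def get_illuminant(name: str) -> Illuminant:
    table = {"D65": d65, "d65": d65, "forestshade": forest_shade}
    if name not in table:
        raise KeyError(f"unknown illuminant {name!r}; choose from D65, forestshade")
    return table[name]()


def passerine_ocular_media(grid: np.ndarray = GRID) -> np.ndarray:
    """Smooth transmission curve approximating a passerine eye's ocular media.

    A logistic short-wavelength cut-off near 320 nm; synthetic
    approximation, not a measured curve.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(grid, float) - 322.0) / 12.0))


# ---------------------------------------------------------------------------
# Visual systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisualSystem:
    """A named receptor set with noise parameters.

    ``relative_abundances`` are the receptor densities eta_i with the
    long-wavelength receptor fixed at 1; the Weber fraction ``w`` applies to
    that reference receptor, so the noise of receptor i is
    ``e_i = w * sqrt(1 / eta_i)``.
    """

    name: str
    labels: tuple[str, ...]
    lambda_max: tuple[float, ...]
    weber_fraction: float
    relative_abundances: tuple[float, ...]
    ocular_media: np.ndarray | None = None  # transmission on GRID
    achromatic_receptor: str = "L"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n not in (3, 4):
            raise ValueError("visual systems here have 3 or 4 receptors")
        if len(self.lambda_max) != n or len(self.relative_abundances) != n:
            raise ValueError("per-receptor fields must have equal length")
        if any(a <= 0 for a in self.relative_abundances):
            raise ValueError("abundances must be positive")
        if self.relative_abundances[self.labels.index(self.achromatic_receptor)] != 1:
            raise ValueError("the reference (L) receptor abundance must be 1")

    @property
    def n_receptors(self) -> int:
        return len(self.labels)

    def sensitivities(self, grid: np.ndarray = GRID) -> np.ndarray:
        """(n_receptors, n_wavelengths) unit-peak sensitivity curves."""
        return np.vstack([pigment_sensitivity(lm, grid) for lm in self.lambda_max])

    def noise(self) -> np.ndarray:
        """Per-receptor noise e_i = w * sqrt(eta_L / eta_i), eta_L = 1."""
        eta = np.asarray(self.relative_abundances, dtype=float)
        return self.weber_fraction * np.sqrt(1.0 / eta)


def builtin_visual_systems() -> dict[str, VisualSystem]:
    """The five observers used throughout: avian VS and *Heliconius* I-IV.

    Avian violet-sensitive: peaks 416/478/542/607 nm, Weber fraction 0.06,
    cone abundances VS 0.25, S 0.5, M 1, L 1, with ocular-media filtering.
    *Heliconius* (Weber fraction 0.05): type I (female *H. erato*)
    355/390/470/555 with 0.09/0.07/0.17/1; type II (male *H. erato*,
    *H. sara*) 390/470/555 with 0.13/0.2/1; type III (female *H. sara*)
    355/390/470/555 with 0.09/0.13/0.2/1; type IV (*H. melpomene*)
    355/470/555 with 0.07/0.26/1.
    """
    return {
        "avian_vs": VisualSystem(
            "avian_vs", ("VS", "S", "M", "L"), (416.0, 478.0, 542.0, 607.0),
            0.06, (0.25, 0.5, 1.0, 1.0), ocular_media=passerine_ocular_media()),
        "heli_i": VisualSystem(
            "heli_i", ("UV1", "UV2", "B", "L"), (355.0, 390.0, 470.0, 555.0),
            0.05, (0.09, 0.07, 0.17, 1.0)),
        "heli_ii": VisualSystem(
            "heli_ii", ("UV2", "B", "L"), (390.0, 470.0, 555.0),
            0.05, (0.13, 0.2, 1.0)),
        "heli_iii": VisualSystem(
            "heli_iii", ("UV1", "UV2", "B", "L"), (355.0, 390.0, 470.0, 555.0),
            0.05, (0.09, 0.13, 0.2, 1.0)),
        "heli_iv": VisualSystem(
            "heli_iv", ("UV1", "B", "L"), (355.0, 470.0, 555.0),
            0.05, (0.07, 0.26, 1.0)),
    }


def derive_abundances(ommatidial_fractions: Sequence[float],
                      receptor_composition: Sequence[dict[str, float]],
                      reference: str = "L") -> dict[str, float]:
    """Whole-eye receptor abundances from ommatidial-type statistics.

    eta_r = sum over ommatidial types of (fraction of type) x (proportion of
    receptor r within the type), then normalized so the reference receptor
    is 1.
    """
    fr = np.asarray(ommatidial_fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("ommatidial fractions must sum to 1")
    for comp in receptor_composition:
        if not np.isclose(sum(comp.values()), 1.0):
            raise ValueError("receptor proportions within a type must sum to 1")
    eta: dict[str, float] = {}
    for f, comp in zip(fr, receptor_composition, strict=True):
        for r, p in comp.items():
            eta[r] = eta.get(r, 0.0) + f * p
    if eta.get(reference, 0.0) == 0:
        raise ValueError(f"reference receptor {reference!r} has zero abundance")
    ref = eta[reference]
    return {r: v / ref for r, v in eta.items()}


# ---------------------------------------------------------------------------
# Quantum catches and colour coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatchVector:
    """Per-receptor quantum catches, ordered as the system's receptors."""

    values: np.ndarray
    system: str
    von_kries: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("quantum catches must be positive and finite")
        object.__setattr__(self, "values", v)


def quantum_catches(spec: Spectrum, system: VisualSystem,
                    illum: Illuminant, von_kries: bool = True) -> CatchVector:
    """Receptor quantum catches of a reflectance under an illuminant.

    Q_i = trapezoidal integral over 300-700 nm of R(lambda) S_i(lambda)
    I(lambda) T_ocular(lambda), with R the reflectance as a fraction of the
    white standard.  With ``von_kries`` each Q_i is divided by the catch of
    a perfect white reflector under the same illuminant, so the adapting
    white maps to unit catches.
    """
    wl = spec.wavelength_nm
    if wl[0] > WORKING_RANGE[0] or wl[-1] < WORKING_RANGE[1]:
        raise ValueError("spectrum must cover the 300-700 nm working range")
    refl = np.interp(GRID, wl, spec.reflectance_pct) / 100.0
    sens = system.sensitivities(GRID)
    weight = illum.irradiance.copy()
    if system.ocular_media is not None:
        weight = weight * system.ocular_media
    q = np.trapezoid(refl * sens * weight, GRID, axis=1)
    if np.any(q <= 0):
        raise ValueError("degenerate stimulus: zero catch for some receptor")
    if von_kries:
        q_white = np.trapezoid(sens * weight, GRID, axis=1)
        q = q / q_white
    return CatchVector(q, system.name, von_kries)


# simplex vertex conventions: regular figures centred on the achromatic
# point with each vertex at distance 0.75 from the centroid
_TETRA_VERTICES = 0.75 / np.sqrt(3.0) * np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
])
_TRI_VERTICES = 0.75 * np.array([
    [0.0, 1.0],
    [-np.sqrt(3.0) / 2.0, -0.5],
    [np.sqrt(3.0) / 2.0, -0.5],
])


@dataclass(frozen=True)
class ColourPoint:
    """Relative catches (sum 1) and their simplex coordinates."""

    relative_catches: np.ndarray
    coordinates: np.ndarray  # (x, y, z) tetrachromat / (x, y) trichromat
    system: str


def colour_point(catches: CatchVector) -> ColourPoint:
    """Embed relative catches in the colour tetrahedron or Maxwell triangle.

    Catches are normalized to sum 1 and mapped as a convex combination of
    regular-simplex vertices placed 0.75 from the centroid (so a stimulus
    exciting a single receptor lies on the corresponding vertex and equal
    catches map to the achromatic origin).
    """
    rel = catches.values / catches.values.sum()
    verts = _TETRA_VERTICES if rel.size == 4 else _TRI_VERTICES
    return ColourPoint(rel, rel @ verts, catches.system)


# ---------------------------------------------------------------------------
# Receptor-noise-limited discriminability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminabilityResult:
    chromatic_jnd: float
    achromatic_jnd: float
    system: str
    illuminant: str
    pair: tuple[str, str] = ("", "")


def _check_pair(a: CatchVector, b: CatchVector, system: VisualSystem) -> None:
    if a.values.size != b.values.size or a.values.size != system.n_receptors:
        raise ValueError("catch vectors and system receptor counts must match")


def rnl_distance(delta_f: np.ndarray, noise: np.ndarray) -> float:
    """Receptor-noise-limited distance of a log-signal difference vector.

    Closed forms of the model for 2, 3 and 4 receptors; ``delta_f`` holds
    the per-receptor log contrasts and ``noise`` the per-receptor noise
    amplitudes e_i.
    """
    df = np.asarray(delta_f, dtype=float)
    e = np.asarray(noise, dtype=float)
    n = df.size
    if n == 2:
        return float(abs(df[0] - df[1]) / np.hypot(e[0], e[1]))
    if n == 3:
        num = (e[0] ** 2 * (df[1] - df[2]) ** 2
               + e[1] ** 2 * (df[0] - df[2]) ** 2
               + e[2] ** 2 * (df[0] - df[1]) ** 2)
        den = ((e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2)
        return float(np.sqrt(num / den))
    # tetrachromat
    num = ((e[0] * e[1]) ** 2 * (df[3] - df[2]) ** 2
           + (e[0] * e[2]) ** 2 * (df[3] - df[1]) ** 2
           + (e[0] * e[3]) ** 2 * (df[2] - df[1]) ** 2
           + (e[1] * e[2]) ** 2 * (df[3] - df[0]) ** 2
           + (e[1] * e[3]) ** 2 * (df[2] - df[0]) ** 2
           + (e[2] * e[3]) ** 2 * (df[1] - df[0]) ** 2)
    den = ((e[0] * e[1] * e[2]) ** 2 + (e[0] * e[1] * e[3]) ** 2
           + (e[0] * e[2] * e[3]) ** 2 + (e[1] * e[2] * e[3]) ** 2)
    return float(np.sqrt(num / den))


def chromatic_jnd(a: CatchVector, b: CatchVector, system: VisualSystem) -> float:
    """Receptor-noise-limited chromatic distance between two stimuli, in JND.

    Log receptor signals delta_f_i = ln(Q_a,i / Q_b,i) are compared under
    independent Gaussian noise e_i = w * sqrt(eta_L / eta_i).  Symmetric,
    invariant to scaling either spectrum, and zero iff the catches are
    proportional.
    """
    _check_pair(a, b, system)
    return rnl_distance(np.log(a.values / b.values), system.noise())


def achromatic_jnd(a: CatchVector, b: CatchVector, system: VisualSystem) -> float:
    """Achromatic JND from the long-wavelength receptor alone.

    |ln(Q_a,L / Q_b,L)| / w — one Weber step is one JND.
    """
    _check_pair(a, b, system)
    i = system.labels.index(system.achromatic_receptor)
    return float(abs(np.log(a.values[i] / b.values[i])) / system.weber_fraction)


def pairwise_discriminability(group_a: Sequence[Spectrum],
                              group_b: Sequence[Spectrum],
                              system: VisualSystem, illum: Illuminant,
                              ) -> list[DiscriminabilityResult]:
    """JNDs for every cross-pair between two groups of spectra.

    Returns |A| x |B| results (16 for the 4-vs-4 co-mimic design); absolute
    (non-von-Kries) catches feed the noise model.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    qa = [quantum_catches(s, system, illum, von_kries=False) for s in group_a]
    qb = [quantum_catches(s, system, illum, von_kries=False) for s in group_b]
    out = []
    for i, ca in enumerate(qa):
        for j, cb in enumerate(qb):
            out.append(DiscriminabilityResult(
                chromatic_jnd(ca, cb, system),
                achromatic_jnd(ca, cb, system),
                system.name, illum.name,
                (group_a[i].individual or str(i), group_b[j].individual or str(j)),
            ))
    return out


def summarize_jnds(results: Sequence[DiscriminabilityResult]) -> dict:
    """Quartile summary of a JND distribution, for box-plot-style reporting."""
    chrom = np.array([r.chromatic_jnd for r in results])
    achro = np.array([r.achromatic_jnd for r in results])
    q = lambda v: dict(zip(("q1", "median", "q3"),
                           np.percentile(v, [25, 50, 75]).tolist()))
    return {"n_pairs": len(results),
            "chromatic": q(chrom), "achromatic": q(achro)}
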