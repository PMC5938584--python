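"""Per-taxon summary tables and the ridge-spacing vs brightness analysis.

Assembles the per-taxon structural and optical descriptors (ridge spacing
from AFM and SAXS, peak wavelength, FWHM, angle and value of maximum
reflectance) and tests the association between mean SAXS ridge spacing and
mean maximum reflectance across taxa with a Pearson correlation, plus
per-clade ordinary-least-squares slopes: more densely packed ridges
(smaller spacing) reflect more light, and the *H. erato* clade gains more
reflectance per unit of ridge density than the *H. melpomene* clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SummaryRow:
    """One taxon's row of structural and optical descriptors.

    ``*_sd`` fields are across-individual sample standard deviations
    (None when only one individual was measured); spacing or angle fields
    are None where the modality was not measured.  ``peak_at_boundary``
    marks taxa whose reflectance still rises at 700 nm ("~700" peaks).
    """

    taxon: str
    ridge_spacing_afm_nm: float | None = None
    ridge_spacing_saxs_nm: float | None = None
    ridge_spacing_saxs_sd: float | None = None
    peak_wavelength_nm: float | None = None
    peak_wavelength_sd: float | None = None
    fwhm_nm: float | None = None
    fwhm_sd: float | None = None
    angle_of_max_deg: float | None = None
    angle_of_max_sd: float | None = None
    max_reflectance_pct: float | None = None
    max_reflectance_sd: float | None = None
    peak_at_boundary: bool = False

    def __post_init__(self) -> None:
        for name in ("ridge_spacing_afm_nm", "ridge_spacing_saxs_nm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ridge_spacing_saxs_sd", "peak_wavelength_sd", "fwhm_sd",
                     "angle_of_max_sd", "max_reflectance_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.max_reflectance_pct is not None
                and self.max_reflectance_pct < 0):
            raise ValueError("max reflectance must be non-negative")


def _mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return float(v.mean()), sd


def build_summary(per_taxon: dict[str, dict[str, Sequence[float]]]
                  ) -> list[SummaryRow]:
    """Per-taxon mean +/- sample s.d. of per-individual descriptors.

    ``per_taxon`` maps a taxon name to a dict of descriptor lists, one
    value per individual; recognized keys are ``ridge_spacing_afm_nm``,
    ``ridge_spacing_saxs_nm``, ``peak_wavelength_nm``, ``fwhm_nm``,
    ``angle_of_max_deg``, ``max_reflectance_pct``.
    """
    rows = []
    for taxon, data in per_taxon.items():
        row = SummaryRow(taxon=taxon)
        if "ridge_spacing_afm_nm" in data:
            row.ridge_spacing_afm_nm, _ = _mean_sd(data["ridge_spacing_afm_nm"])
        for key, mean_attr, sd_attr in (
            ("ridge_spacing_saxs_nm", "ridge_spacing_saxs_nm",
             "ridge_spacing_saxs_sd"),
            ("peak_wavelength_nm", "peak_wavelength_nm", "peak_wavelength_sd"),
            ("fwhm_nm", "fwhm_nm", "fwhm_sd"),
            ("angle_of_max_deg", "angle_of_max_deg", "angle_of_max_sd"),
            ("max_reflectance_pct", "max_reflectance_pct",
             "max_reflectance_sd"),
        ):
            if key in data and len(data[key]) > 0:
                m, sd = _mean_sd(data[key])
                setattr(row, mean_attr, m)
                setattr(row, sd_attr, sd)
        rows.append(row)
    return rows


def pearson_with_p(x: Sequence[float], y: Sequence[float]
                   ) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value.

    p comes from t = r sqrt((n-2)/(1-r^2)) against Student's t with n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3 values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# clade membership for the per-clade slope contrast
ERATO_GROUP = ("H. erato demophoon", "H. erato cyrbia", "H. sara (Ecuador)",
               "H. sara (Panama)", "H. eleuchia")
MELPOMENE_GROUP = ("H. cydno", "H. melpomene cythera", "H. melpomene rosina")


@dataclass(frozen=True)
class SpacingReflectanceResult:
    r: float
    p: float
    n: int
    slopes: dict[str, float]


def spacing_reflectance_analysis(
        rows: Sequence[SummaryRow],
        clades: dict[str, Sequence[str]] | None = None,
) -> SpacingReflectanceResult:
    """Association of mean SAXS ridge spacing with mean maximum reflectance.

    Taxa lacking either field are dropped.  Returns the global Pearson r
    and p across taxa plus the OLS slope (% reflectance per nm of spacing)
    fitted separately within each configured clade.
    """
    if clades is None:
        clades = {"erato_group": ERATO_GROUP,
                  "melpomene_group": MELPOMENE_GROUP}
    use = [row for row in rows
           if row.ridge_spacing_saxs_nm is not None
           and row.max_reflectance_pct is not None]
    if len(use) < 3:
        raise ValueError("need at least 3 taxa with both spacing and reflectance")
    x = [row.ridge_spacing_saxs_nm for row in use]
    y = [row.max_reflectance_pct for row in use]
    r, p = pearson_with_p(x, y)
    slopes = {}
    for clade, members in clades.items():
        sub = [row for row in use if row.taxon in members]
        if len(sub) >= 2:
            xs = np.array([row.ridge_spacing_saxs_nm for row in sub])
            ys = np.array([row.max_reflectance_pct for row in sub])
            slopes[clade] = float(np.polyfit(xs, ys, 1)[0])
    return SpacingReflectanceResult(r, p, len(use), slopes)


_TSV_COLUMNS = [
    "taxon", "ridge_spacing_afm_nm", "ridge_spacing_saxs_nm",
    "ridge_spacing_saxs_sd", "peak_wavelength_nm", "peak_wavelength_sd",
    "fwhm_nm", "fwhm_sd", "angle_of_max_deg", "angle_of_max_sd",
    "max_reflectance_pct", "max_reflectance_sd", "peak_at_boundary",
]


def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a DataFrame in the canonical column order."""
    return pd.DataFrame([{c: getattr(row, c) for c in _TSV_COLUMNS}
                         for row in rows])


def write_summary_tsv(rows: Sequence[SummaryRow], path) -> None:
    summary_to_frame(rows).to_csv(path, sep="\t", index=False)
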