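"""Lipid-peroxidation assays: conjugated dienes and TBARS.

Two spectrophotometric readouts complement the FTIR markers:

* **Conjugated dienes (CD)** — primary peroxidation products absorbing at
  233 nm, converted to molar concentration by Beer-Lambert with the molar
  extinction coefficient 27000 M^-1 cm^-1 and reported as uM per million
  cells.
* **TBARS** — malondialdehyde(MDA)-equivalent secondary products read at
  532 nm against a tetramethoxypropane (TMP) calibration line (standards
  1.25-20 uM; TMP hydrolyses to MDA 1:1). The calibration is fit as
  absorbance-on-concentration by ordinary least squares and inverted,
  the standard analytical-chemistry direction; both directions coincide
  exactly when R^2 = 1.

Blank subtraction is assumed done upstream of the absorbance inputs.
Negative back-calculated concentrations are reported with a flag rather
than clipped, so group statistics keep the full information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import AssayTable

__all__ = [
    "MOLAR_EXTINCTION_CD",
    "TMP_STANDARDS_UM",
    "CalibrationCurve",
    "AssayResult",
    "cd_concentration",
    "fit_tbars_calibration",
    "tbars_concentration",
    "assay_table_results",
]

#: Molar extinction coefficient of conjugated dienes at 233 nm (M^-1 cm^-1).
MOLAR_EXTINCTION_CD = 27000.0

#: Canonical TMP/MDA calibration concentrations (uM).
TMP_STANDARDS_UM = (1.25, 2.5, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line absorbance = slope * concentration(uM) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple[tuple[float, float], ...]  # (concentration uM, absorbance)

    def predict(self, concentration_um: float) -> float:
        return self.slope * concentration_um + self.intercept

    def invert(self, absorbance: float) -> float:
        if self.slope == 0.0:
            raise ZeroDivisionError("calibration slope is zero; cannot invert")
        return (absorbance - self.intercept) / self.slope

    @property
    def concentration_range(self) -> tuple[float, float]:
        concs = [c for c, _ in self.standards]
        return min(concs), max(concs)


@dataclass(frozen=True)
class AssayResult:
    """One sample's assay readout, normalized per million cells."""

    sample_id: str
    treatment: str
    concentration_per_million_cells: float  # uM per 1e6 cells
    assay: str  # "CD" | "TBARS"
    flagged: bool = False  # negative back-calculated concentration

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration_per_million_cells):
            raise ValueError("assay concentration must be finite")
        if self.assay not in ("CD", "TBARS"):
            raise ValueError(f"assay must be 'CD' or 'TBARS', got {self.assay!r}")


def cd_concentration(
    absorbance_233nm: float,
    path_cm: float = 1.0,
    cells_millions: float = 1.0,
    sample_id: str = "",
    treatment: str = "",
) -> AssayResult:
    """Conjugated-diene concentration from a 233 nm absorbance.

    Beer-Lambert: molar concentration A / (27000 * path), converted to uM
    and divided by the number of cells in millions. Linear and homogeneous
    in absorbance, exactly inverse-proportional in the cell count.
    """
    if not np.isfinite(absorbance_233nm):
        raise ValueError("absorbance must be finite")
    if path_cm <= 0:
        raise ValueError(f"path length must be positive, got {path_cm}")
    if cells_millions <= 0:
        raise ValueError(f"cells_millions must be positive, got {cells_millions}")
    conc_um = absorbance_233nm / (MOLAR_EXTINCTION_CD * path_cm) * 1e6
    value = conc_um / cells_millions
    return AssayResult(sample_id, treatment, value, "CD", flagged=value < 0)


def fit_tbars_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Fit the TMP/MDA calibration line by ordinary least squares.

    ``standards`` are (concentration uM, absorbance) pairs; at least two
    distinct concentrations are required. R^2 is the squared Pearson
    correlation of the fit (1 for a noiseless line, including the
    two-point case).
    """
    standards = tuple((float(c), float(a)) for c, a in standards)
    concs = np.array([c for c, _ in standards])
    absorb = np.array([a for _, a in standards])
    if np.unique(concs).size < 2:
        raise ValueError(
            "calibration needs >= 2 distinct standard concentrations"
        )
    fit = stats.linregress(concs, absorb)
    r2 = 1.0 if np.ptp(absorb) == 0 else float(fit.rvalue**2)
    return CalibrationCurve(float(fit.slope), float(fit.intercept), r2, standards)


def tbars_concentration(
    absorbance_532nm: float,
    curve: CalibrationCurve,
    cells_millions: float = 1.0,
    sample_id: str = "",
    treatment: str = "",
) -> AssayResult:
    """MDA-equivalent concentration from a 532 nm absorbance.

    Inverts the calibration line and divides by the cell count. Absorbances
    implying a concentration beyond twice the calibrated range raise a
    warning (extrapolation), never an error.
    """
    if not np.isfinite(absorbance_532nm):
        raise ValueError("absorbance must be finite")
    if cells_millions <= 0:
        raise ValueError(f"cells_millions must be positive, got {cells_millions}")
    conc_um = curve.invert(absorbance_532nm)
    lo, hi = curve.concentration_range
    if not (-2 * hi) <= conc_um <= 2 * hi:
        warnings.warn(
            f"absorbance {absorbance_532nm:g} implies {conc_um:g} uM, outside "
            f"2x the calibrated range [{lo:g}, {hi:g}] uM",
            stacklevel=2,
        )
    value = conc_um / cells_millions
    return AssayResult(sample_id, treatment, value, "TBARS", flagged=value < 0)


def assay_table_results(
    table: AssayTable,
    assay: str,
    curve: CalibrationCurve | None = None,
    path_cm: float = 1.0,
) -> pd.DataFrame:
    """Convert a whole assay table to per-million-cell concentrations.

    ``assay`` is ``"CD"`` (Beer-Lambert; ``path_cm`` applies) or
    ``"TBARS"`` (requires a fitted ``curve``). Returns a tidy frame with
    columns sample_id, treatment, assay, concentration_per_million_cells,
    flagged.
    """
    rows = []
    for rec in table.frame.itertuples(index=False):
        if assay == "CD":
            res = cd_concentration(rec.absorbance, path_cm, rec.cells_millions,
                                   rec.sample_id, rec.treatment)
        elif assay == "TBARS":
            if curve is None:
                raise ValueError("TBARS conversion requires a calibration curve")
            res = tbars_concentration(rec.absorbance, curve, rec.cells_millions,
                                      rec.sample_id, rec.treatment)
        else:
            raise ValueError(f"assay must be 'CD' or 'TBARS', got {assay!r}")
        rows.append(
            {
                "sample_id": res.sample_id,
                "treatment": res.treatment,
                "assay": res.assay,
                "concentration_per_million_cells":
                    res.concentration_per_million_cells,
                "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)
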