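"""Band-ratio markers of oxidative stress from second-derivative spectra.

Four ratios of characteristic band intensities track the biochemical
signature of H2O2-induced oxidative damage in cells:

==================  =================  =========================================
marker              bands (cm^-1)      reads out
==================  =================  =========================================
lipid_oxidation     1740 / 2960        carbonyl/aldehyde accumulation from
                                       lipid peroxidation
lipid_saturation    2920 / 2960        CH2 vs CH3 asymmetric stretch — acyl
                                       chain saturation state
lipid_desaturation  3012 / 2960        olefinic =C-H vs CH3 — unsaturated
                                       lipid content
protein_aggregation 1630 / 1650        beta-sheet-like shoulder vs alpha-helical
                                       amide I — protein aggregation
==================  =================  =========================================

Band intensity is taken as the magnitude of the deepest second-derivative
minimum inside a +-halfwidth search window around the nominal centre, not
the value at the exact grid point: instrument calibration drifts by a few
cm^-1 and the bands are named, not pinned to grid points. Second-derivative
band intensities are negative at absorption maxima, so magnitudes keep the
reported ratios positive. All four markers are invariant to positive global
rescaling of the raw spectrum (the normalization step therefore cannot
change them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_io import Spectrum

__all__ = [
    "BandDef",
    "MarkerPanel",
    "EffectLabel",
    "CANONICAL_BANDS",
    "MARKER_RATIOS",
    "MARKER_NAMES",
    "band_amplitude",
    "marker_panel",
    "panels_to_frame",
    "relative_to_control",
    "classify_effect",
]

logger = logging.getLogger(__name__)

#: Default half-width (cm^-1) of the band search window.
DEFAULT_HALFWIDTH = 8.0


@dataclass(frozen=True)
class BandDef:
    """A named absorption band with its search window half-width."""

    name: str
    center: float
    halfwidth: float = DEFAULT_HALFWIDTH

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError(f"halfwidth must be positive, got {self.halfwidth}")


def canonical_bands(halfwidth: float = DEFAULT_HALFWIDTH) -> dict[str, BandDef]:
    """The six marker bands, keyed by nominal centre."""
    return {
        "1740": BandDef("ester/aldehyde C=O", 1740.0, halfwidth),
        "2960": BandDef("CH3 asym stretch", 2960.0, halfwidth),
        "2920": BandDef("CH2 asym stretch", 2920.0, halfwidth),
        "3012": BandDef("olefinic =C-H", 3012.0, halfwidth),
        "1650": BandDef("amide I (alpha)", 1650.0, halfwidth),
        "1630": BandDef("amide I (beta-sheet)", 1630.0, halfwidth),
    }


CANONICAL_BANDS = canonical_bands()

#: marker name -> (numerator band key, denominator band key)
MARKER_RATIOS: dict[str, tuple[str, str]] = {
    "lipid_oxidation": ("1740", "2960"),
    "lipid_saturation": ("2920", "2960"),
    "lipid_desaturation": ("3012", "2960"),
    "protein_aggregation": ("1630", "1650"),
}

MARKER_NAMES = tuple(MARKER_RATIOS)


@dataclass(frozen=True)
class MarkerPanel:
    """The four band-ratio markers for one spectrum."""

    sample_id: str
    treatment: str
    lipid_oxidation: float
    lipid_saturation: float
    lipid_desaturation: float
    protein_aggregation: float

    def __post_init__(self) -> None:
        for m in MARKER_NAMES:
            v = getattr(self, m)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{m} must be finite and nonnegative, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MARKER_NAMES}


@dataclass(frozen=True)
class EffectLabel:
    """Classification of a treatment's effect on one marker."""

    marker: str
    label: str  # protective | partial | no_effect | stress_like


def band_amplitude(
    d: Spectrum, band: BandDef, exact_point: bool = False
) -> float:
    """Magnitude of the band's second-derivative minimum.

    Searches the closed window ``center +- halfwidth``; ties between equal
    minima break toward the wavenumber nearest the nominal centre. With
    ``exact_point=True`` the magnitude at the grid point nearest the centre
    is returned instead (a sensitivity-check variant).

    A window containing no negative value yields the magnitude of the
    global window minimum, with a logged warning — on real second
    derivatives that indicates a band absent from the spectrum.
    """
    if d.kind != "second_derivative":
        raise ValueError(
            f"band_amplitude needs a second-derivative spectrum, got kind={d.kind!r}"
        )
    lo, hi = band.center - band.halfwidth, band.center + band.halfwidth
    if lo < d.wavenumbers[0] or hi > d.wavenumbers[-1]:
        raise ValueError(
            f"band window [{lo}, {hi}] outside grid "
            f"[{d.wavenumbers[0]}, {d.wavenumbers[-1]}]"
        )
    if exact_point:
        idx = int(np.argmin(np.abs(d.wavenumbers - band.center)))
        return float(abs(d.intensities[idx]))
    mask = (d.wavenumbers >= lo) & (d.wavenumbers <= hi)
    window = d.intensities[mask]
    wn = d.wavenumbers[mask]
    vmin = float(window.min())
    if vmin >= 0:
        logger.warning(
            "no negative second-derivative value near %s (%g cm^-1) in %s",
            band.name, band.center, d.sample_id,
        )
    ties = np.flatnonzero(window == vmin)
    best = ties[np.argmin(np.abs(wn[ties] - band.center))]
    return float(abs(window[best]))


def marker_panel(
    d: Spectrum,
    bands: Mapping[str, BandDef] | None = None,
    exact_point: bool = False,
) -> MarkerPanel:
    """Compute the four-ratio marker panel for one second-derivative spectrum."""
    bands = dict(bands) if bands is not None else CANONICAL_BANDS
    amps = {key: band_amplitude(d, b, exact_point=exact_point)
            for key, b in bands.items()}
    values = {}
    for marker, (num, den) in MARKER_RATIOS.items():
        if amps[den] == 0.0:
            raise ValueError(
                f"degenerate spectrum {d.sample_id!r}: zero amplitude at the "
                f"{den} cm^-1 reference band"
            )
        values[marker] = amps[num] / amps[den]
    return MarkerPanel(sample_id=d.sample_id, treatment=d.treatment, **values)


def panels_to_frame(panels: Iterable[MarkerPanel]) -> pd.DataFrame:
    """Tidy frame: sample_id, treatment, marker, value."""
    rows = [
        {"sample_id": p.sample_id, "treatment": p.treatment, "marker": m,
         "value": getattr(p, m)}
        for p in panels
        for m in MARKER_NAMES
    ]
    return pd.DataFrame(rows)


def relative_to_control(
    panels: Sequence[MarkerPanel], control_label: str
) -> list[MarkerPanel]:
    """Divide every marker by the control-group mean of that marker.

    The control group maps to mean 1 per marker by construction, mirroring
    the convention of plotting each ratio against a dotted control line.
    """
    controls = [p for p in panels if p.treatment == control_label]
    if not controls:
        raise ValueError(f"no panels with control label {control_label!r}")
    means = {m: float(np.mean([getattr(p, m) for p in controls]))
             for m in MARKER_NAMES}
    for m, mu in means.items():
        if mu == 0.0:
            raise ValueError(f"control mean of {m} is zero; cannot normalize")
    return [
        MarkerPanel(
            sample_id=p.sample_id,
            treatment=p.treatment,
            **{m: getattr(p, m) / means[m] for m in MARKER_NAMES},
        )
        for p in panels
    ]


def classify_effect(
    treatment_mean: float,
    control_mean: float,
    stress_mean: float,
    tol: float = 0.15,
    marker: str = "",
) -> EffectLabel:
    """Place a treatment mean on the control-to-stress axis.

    The position ``p = (treatment - control) / (stress - control)`` is 0 for
    a mean at control level and 1 at the stressed level. ``p <= tol`` reads
    as protective, ``p >= 1 - tol`` as stress-like, anything between as
    partial protection. If stress and control are themselves closer than
    ``tol * control``, the marker distinguishes nothing and every treatment
    is labelled ``no_effect``. The rule is invariant to jointly rescaling
    all three means.
    """
    vals = (treatment_mean, control_mean, stress_mean)
    if not all(np.isfinite(vals)):
        raise ValueError(f"non-finite inputs to classify_effect: {vals}")
    if abs(stress_mean - control_mean) < tol * abs(control_mean):
        return EffectLabel(marker, "no_effect")
    if control_mean == stress_mean:
        raise ValueError("control_mean and stress_mean must differ")
    p = (treatment_mean - control_mean) / (stress_mean - control_mean)
    if p <= tol:
        label = "protective"
    elif p >= 1 - tol:
        label = "stress_like"
    else:
        label = "partial"
    return EffectLabel(marker, label)
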