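"""Spectral preprocessing: vector normalization, SG differentiation, cropping.

The processing chain is fixed and order-sensitive: spectra are first scaled
to unit Euclidean norm over the full recorded range (removing pathlength and
cell-mass differences between samples), and only then differentiated twice
with a Savitzky-Golay filter (default: 21-point window, quadratic
polynomial), which resolves overlapping absorption bands — band maxima
appear as sharp negative minima in the second derivative. Region cropping
comes last, so that normalization always sees the whole spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .spectra_io import Spectrum, SpectraCollection

__all__ = [
    "SGFilterSpec",
    "vector_normalize",
    "sg_coefficients",
    "second_derivative",
    "crop_region",
    "preprocess_collection",
]

#: Relative tolerance on grid-step uniformity before SG differentiation.
GRID_UNIFORMITY_RTOL = 1e-3


@dataclass(frozen=True)
class SGFilterSpec:
    """Savitzky-Golay filter parameters.

    window
        Odd number of points in the moving least-squares window. The
        default 21 points on a 2 cm^-1 grid spans 40 cm^-1, matching the
        smoothing customarily applied to ~6 cm^-1-resolution cell spectra.
    polyorder
        Degree of the local polynomial (default 2).
    deriv
        Derivative order estimated at the window centre (default 2).
    delta
        Grid spacing in cm^-1 used to scale the derivative to per-cm^-1
        units; ``None`` means "take it from the spectrum's grid".
    """

    window: int = 21
    polyorder: int = 2
    deriv: int = 2
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if not (0 <= self.polyorder < self.window):
            raise ValueError(
                f"polyorder must satisfy 0 <= polyorder < window, got {self.polyorder}"
            )
        if not (0 <= self.deriv <= self.polyorder):
            raise ValueError(
                f"deriv must satisfy 0 <= deriv <= polyorder, got {self.deriv}"
            )
        if self.delta is not None and self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale a spectrum to unit Euclidean norm.

    Idempotent and invariant to positive rescaling of the input; the
    all-zero spectrum is rejected as degenerate.
    """
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise ValueError(f"cannot normalize all-zero spectrum {s.sample_id!r}")
    return s.with_intensities(s.intensities / norm, kind="normalized")


def sg_coefficients(spec: SGFilterSpec) -> np.ndarray:
    """Weights of the SG derivative estimator at the window centre.

    Returned in ascending-index order (apply by dotting with the window
    values), scaled per index step: multiply the dot product by
    ``1/delta**deriv`` to obtain a derivative per physical unit. For the
    classic (window=5, polyorder=2, deriv=2) case these are
    ``(2, -1, -2, -1, 2)/7``.
    """
    return savgol_coeffs(spec.window, spec.polyorder, deriv=spec.deriv,
                         delta=1.0, use="dot")


def second_derivative(s: Spectrum, spec: SGFilterSpec | None = None) -> Spectrum:
    """Savitzky-Golay derivative of a (normalized) spectrum.

    The filter needs a uniform grid (within 0.1% of the median step);
    non-uniform grids must be resampled first. Half-windows at both edges
    are trimmed rather than padded — the output grid is ``window - 1``
    points shorter — because padding would invent data and no marker band
    sits near the acquisition edges. Output units are per cm^-1 to the
    power ``deriv``.
    """
    spec = spec or SGFilterSpec()
    if s.kind != "normalized":
        warnings.warn(
            f"second_derivative expects a normalized spectrum, got kind={s.kind!r}",
            stacklevel=2,
        )
    if len(s) < spec.window:
        raise ValueError(
            f"spectrum has {len(s)} points, fewer than the {spec.window}-point window"
        )
    steps = np.diff(s.wavenumbers)
    median_step = float(np.median(steps))
    if np.any(np.abs(steps - median_step) > GRID_UNIFORMITY_RTOL * median_step):
        raise ValueError(
            "grid is not uniform within 0.1% of the median step; "
            "use resample_to_grid first"
        )
    delta = spec.delta if spec.delta is not None else median_step
    d = savgol_filter(s.intensities, spec.window, spec.polyorder,
                      deriv=spec.deriv, delta=delta)
    half = spec.window // 2
    return replace(
        s,
        wavenumbers=s.wavenumbers[half:-half],
        intensities=d[half:-half],
        kind="second_derivative",
    )


def crop_region(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Slice a spectrum to the closed wavenumber interval [lo, hi]."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"region [{lo}, {hi}] does not overlap the grid "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return replace(s, wavenumbers=s.wavenumbers[mask], intensities=s.intensities[mask])


def preprocess_collection(
    c: SpectraCollection, spec: SGFilterSpec | None = None
) -> SpectraCollection:
    """Normalize then differentiate every spectrum in a collection."""
    spec = spec or SGFilterSpec()
    return c.map(lambda s: second_derivative(vector_normalize(s), spec))
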