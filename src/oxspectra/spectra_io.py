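"""Reading, writing and regridding of FTIR spectra and assay tables.

The carriers defined here are used by every other module:

* :class:`Spectrum` — a single absorbance trace on a strictly ascending
  wavenumber grid, tagged with its processing state (``raw`` →
  ``normalized`` → ``second_derivative``).
* :class:`SpectraCollection` — spectra sharing one grid, with a mapping
  from treatment label to member sample ids.
* :class:`AssayTable` — per-sample absorbance readings with cell counts,
  used by the conjugated-diene and TBARS quantification.

Supported text formats: wide/long CSV, a minimal JCAMP-DX dialect
(AFFN ``##XYDATA=(X++(Y..Y))``), and a YAML sidecar for group membership.
All readers emit ascending grids regardless of the on-disk order, because
unambiguous slicing and interpolation need a canonical direction even
though spectroscopists conventionally plot wavenumbers descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Spectrum",
    "SpectraCollection",
    "AssayTable",
    "SpectraFormatError",
    "GridMismatchError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "read_assay_csv",
    "write_assay_csv",
    "resample_to_grid",
]

#: Allowed processing states, in pipeline order.
KINDS = ("raw", "normalized", "second_derivative")


class SpectraFormatError(ValueError):
    """A file does not conform to the expected spectral format."""


class GridMismatchError(ValueError):
    """Spectra are not on a common wavenumber grid."""


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: absorbance (or a derivative thereof) vs wavenumber.

    Parameters
    ----------
    wavenumbers : array, cm^-1, strictly ascending
    intensities : array, same length, absorbance in arbitrary units
    sample_id : identifier of the measured cell population
    treatment : treatment-group label, e.g. ``"control"``, ``"H2O2"``,
        ``"Cat+H2O2"``
    kind : processing state, one of ``raw``, ``normalized``,
        ``second_derivative``
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    treatment: str = ""
    kind: str = "raw"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.ndim != 1 or wn.size != y.size:
            raise ValueError(
                f"wavenumbers and intensities must be 1-D and equally long "
                f"(got {wn.shape} vs {y.shape})"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray, kind: str | None = None) -> "Spectrum":
        """Copy with new intensities (and optionally a new processing state)."""
        return replace(self, intensities=np.asarray(y, float),
                       kind=self.kind if kind is None else kind)


@dataclass
class SpectraCollection:
    """Spectra on one shared grid, grouped by treatment.

    ``groups`` maps each treatment label to its member sample ids; every
    sample id belongs to exactly one group.
    """

    spectra: list[Spectrum]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectra:
            ref = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if s.wavenumbers.shape != ref.shape or not np.array_equal(
                    s.wavenumbers, ref
                ):
                    raise GridMismatchError(
                        f"sample {s.sample_id!r} is on a different grid; "
                        "use resample_to_grid"
                    )
        if not self.groups:
            self.groups = {}
            for s in self.spectra:
                self.groups.setdefault(s.treatment, []).append(s.sample_id)
        seen: dict[str, str] = {}
        for label, members in self.groups.items():
            for sid in members:
                if sid in seen:
                    raise ValueError(
                        f"sample {sid!r} appears in groups {seen[sid]!r} and {label!r}"
                    )
                seen[sid] = label

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def wavenumbers(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty collection has no grid")
        return self.spectra[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_samples, n_points) matrix."""
        return np.vstack([s.intensities for s in self.spectra])

    def get(self, sample_id: str) -> Spectrum:
        for s in self.spectra:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, treatments: Iterable[str]) -> "SpectraCollection":
        keep = set(treatments)
        spectra = [s for s in self.spectra if s.treatment in keep]
        groups = {t: list(m) for t, m in self.groups.items() if t in keep}
        return SpectraCollection(spectra, groups)

    def map(self, fn) -> "SpectraCollection":
        """Apply a Spectrum -> Spectrum transform to every member."""
        return SpectraCollection([fn(s) for s in self.spectra],
                                 {t: list(m) for t, m in self.groups.items()})


@dataclass
class AssayTable:
    """Absorbance readings with matched cell counts (millions of cells)."""

    frame: pd.DataFrame  # columns: sample_id, treatment, absorbance, cells_millions

    REQUIRED = ("sample_id", "treatment", "absorbance", "cells_millions")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"assay table missing columns {missing}")
        if not np.all(np.isfinite(self.frame["absorbance"])):
            raise ValueError("absorbance values must be finite")
        if not np.all(self.frame["cells_millions"] > 0):
            raise ValueError("cells_millions must be positive")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _split_header(header: str) -> tuple[str, str]:
    """Decode the ``sampleid|treatment`` wide-CSV header convention."""
    if "|" in header:
        sid, treatment = header.split("|", 1)
        return sid.strip(), treatment.strip()
    return header.strip(), ""


def read_spectra_csv(
    path: str | Path,
    layout: str = "wide",
    sidecar: str | Path | None = None,
) -> SpectraCollection:
    """Read a spectra collection from CSV.

    ``wide`` layout: first column is the wavenumber, one column per sample;
    sample headers may carry the treatment as ``sampleid|treatment``, or a
    YAML ``sidecar`` file may map treatment labels to sample-id lists.
    ``long`` layout: columns (sample_id, treatment, wavenumber, intensity).

    Descending on-disk grids are reversed; all samples must share one grid
    (otherwise resample first).
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    side_groups: dict[str, str] = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            raw = yaml.safe_load(fh) or {}
        groups = raw.get("groups", raw)
        for label, members in groups.items():
            for sid in members:
                side_groups[str(sid)] = str(label)

    if layout == "wide":
        df = pd.read_csv(path)
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, plus header line
                raise SpectraFormatError(
                    f"non-numeric value in column {col!r} at line {row} of {path}"
                )
            df[col] = coerced
        wn = df.iloc[:, 0].to_numpy(float)
        order = slice(None)
        if wn.size >= 2 and wn[0] > wn[-1]:
            order = slice(None, None, -1)
        wn = wn[order]
        spectra = []
        for col in df.columns[1:]:
            sid, treatment = _split_header(str(col))
            treatment = side_groups.get(sid, treatment)
            spectra.append(
                Spectrum(wn, df[col].to_numpy(float)[order], sample_id=sid,
                         treatment=treatment)
            )
        return SpectraCollection(spectra)

    df = pd.read_csv(path)
    needed = {"sample_id", "treatment", "wavenumber", "intensity"}
    if not needed.issubset(df.columns):
        raise SpectraFormatError(
            f"long layout requires columns {sorted(needed)}, "
            f"found {list(df.columns)}"
        )
    spectra = []
    ref_grid: np.ndarray | None = None
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("wavenumber")
        wn = sub["wavenumber"].to_numpy(float)
        if ref_grid is None:
            ref_grid = wn
        elif wn.shape != ref_grid.shape or not np.array_equal(wn, ref_grid):
            raise GridMismatchError(
                f"grids differ; use resample_to_grid (sample {sid!r})"
            )
        treatment = side_groups.get(str(sid), str(sub["treatment"].iloc[0]))
        spectra.append(
            Spectrum(wn, sub["intensity"].to_numpy(float), sample_id=str(sid),
                     treatment=treatment)
        )
    return SpectraCollection(spectra)


def write_spectra_csv(
    collection: SpectraCollection, path: str | Path, layout: str = "wide"
) -> None:
    """Write a collection to CSV; intensities keep 12 significant digits."""
    path = Path(path)
    if layout == "wide":
        data = {"wavenumber": collection.wavenumbers}
        for s in collection:
            header = f"{s.sample_id}|{s.treatment}" if s.treatment else s.sample_id
            data[header] = s.intensities
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    elif layout == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "treatment": s.treatment,
                    "wavenumber": s.wavenumbers,
                    "intensity": s.intensities,
                }
            )
            for s in collection
        ]
        pd.concat(frames).to_csv(path, index=False, float_format="%.12g")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_assay_csv(path: str | Path) -> AssayTable:
    return AssayTable(pd.read_csv(path))


def write_assay_csv(table: AssayTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN X++(Y..Y) dialect, read-only)
# ---------------------------------------------------------------------------

_JCAMP_REQUIRED = ("FIRSTX", "LASTX", "NPOINTS", "XFACTOR", "YFACTOR")


def read_jcamp(path: str | Path) -> Spectrum:
    """Read one spectrum from a minimal JCAMP-DX file.

    Only the uncompressed AFFN ``##XYDATA=(X++(Y..Y))`` form is supported.
    The wavenumber axis is reconstructed from ``##FIRSTX``, ``##LASTX`` and
    ``##NPOINTS``; ``##XFACTOR``/``##YFACTOR`` are applied to the tabulated
    values. Descending files come back ascending.
    """
    labels: dict[str, str] = {}
    ydata: list[float] = []
    in_data = False
    title = ""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "END":
                break
            if key == "TITLE":
                title = value
            if key == "XYDATA":
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise SpectraFormatError(
                        f"unsupported XYDATA form {value!r}; only (X++(Y..Y))"
                    )
                in_data = True
                continue
            in_data = False
            labels[key] = value
        elif in_data:
            parts = line.replace(",", " ").split()
            # first number on each data line is the abscissa; the rest are Y
            ydata.extend(float(p) for p in parts[1:])

    for req in _JCAMP_REQUIRED:
        if req not in labels:
            raise SpectraFormatError(f"JCAMP file missing mandatory label ##{req}")
    if not ydata:
        raise SpectraFormatError("JCAMP file contains no XYDATA block")

    npoints = int(float(labels["NPOINTS"]))
    firstx = float(labels["FIRSTX"]) * float(labels["XFACTOR"])
    lastx = float(labels["LASTX"]) * float(labels["XFACTOR"])
    if len(ydata) != npoints:
        raise SpectraFormatError(
            f"##NPOINTS={npoints} but {len(ydata)} ordinates found"
        )
    y = np.asarray(ydata, float) * float(labels["YFACTOR"])
    x = np.linspace(firstx, lastx, npoints)
    if npoints >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(x, y, sample_id=title or Path(path).stem)


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def resample_to_grid(
    collection: SpectraCollection, grid: Sequence[float]
) -> SpectraCollection:
    """Linearly interpolate every spectrum onto ``grid``.

    No extrapolation: the target grid must lie inside each source range.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or (grid.size >= 2 and not np.all(np.diff(grid) > 0)):
        raise ValueError("target grid must be 1-D and strictly ascending")
    out = []
    for s in collection:
        lo, hi = s.wavenumbers[0], s.wavenumbers[-1]
        if grid[0] < lo or grid[-1] > hi:
            raise ValueError(
                f"target grid [{grid[0]}, {grid[-1]}] extends outside the "
                f"range [{lo}, {hi}] of sample {s.sample_id!r}"
            )
        y = np.interp(grid, s.wavenumbers, s.intensities)
        out.append(replace(s, wavenumbers=grid, intensities=y))
    return SpectraCollection(out, {t: list(m) for t, m in collection.groups.items()})
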