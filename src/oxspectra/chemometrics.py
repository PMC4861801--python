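"""Region-restricted PCA of spectra collections.

PCA is run on preprocessed (vector-normalized, second-derivative) spectra
over one of three canonical windows — the full range, the fingerprint
region (proteins and nucleic acids) or the C-H stretch lipid region — and
returns scores, loadings and explained-variance fractions for score-plot /
loading-plot chemometrics. Mean-centering only, no per-wavenumber variance
scaling: unit-variance scaling would erase the band-intensity structure the
loadings are meant to reveal.

The decomposition is a plain singular value decomposition of the centered
data matrix with a deterministic sign convention (each loading's
largest-magnitude element is made positive), so scores and loadings are
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .spectra_io import Spectrum, SpectraCollection
from .preprocess import crop_region

__all__ = ["PCAResult", "REGION_PRESETS", "pca", "project", "group_centroids"]

#: Canonical analysis windows (lo, hi) in cm^-1.
REGION_PRESETS: dict[str, tuple[float, float]] = {
    "full": (900.0, 4000.0),
    "fingerprint": (900.0, 1900.0),
    "lipid": (2800.0, 3200.0),
}


@dataclass
class PCAResult:
    """Mean-centered PCA of a spectra collection over one spectral window."""

    region: tuple[float, float]
    wavenumbers: np.ndarray          # (p,) grid of the analyzed window
    mean_spectrum: np.ndarray        # (p,)
    loadings: np.ndarray             # (k, p), rows orthonormal
    scores: np.ndarray               # (n, k)
    explained_variance_fraction: np.ndarray  # (k,), nonincreasing
    sample_ids: list[str]
    groups: dict[str, list[str]]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def cumulative_variance(self, k: int | None = None) -> float:
        k = self.n_components if k is None else k
        return float(self.explained_variance_fraction[:k].sum())


def _resolve_region(region) -> tuple[float, float]:
    if isinstance(region, str):
        try:
            return REGION_PRESETS[region]
        except KeyError:
            raise ValueError(
                f"unknown region preset {region!r}; choose from "
                f"{sorted(REGION_PRESETS)}"
            ) from None
    lo, hi = region
    return float(lo), float(hi)


def pca(
    c: SpectraCollection,
    region: str | tuple[float, float] = "full",
    n_components: int = 2,
) -> PCAResult:
    """Principal component analysis over a spectral window.

    Spectra are cropped to the closed interval ``region`` (a preset name or
    an explicit (lo, hi) pair), column-mean-centered and decomposed by SVD.
    Explained-variance fractions are singular values squared over their
    total, so they sum to 1 over all components.
    """
    if len(c) < 2:
        raise ValueError(f"PCA needs at least 2 spectra, got {len(c)}")
    lo, hi = _resolve_region(region)
    cropped = c.map(lambda s: crop_region(s, lo, hi))
    X = cropped.intensity_matrix()
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError(
            "zero total variance: all spectra in the collection are identical"
        )
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(svals**2))
    k = min(n_components, svals.size)
    loadings = Vt[:k]
    scores = U[:, :k] * svals[:k]
    # deterministic orientation: largest-|.| element of each loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        region=(lo, hi),
        wavenumbers=cropped.wavenumbers,
        mean_spectrum=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=svals[:k] ** 2 / total,
        sample_ids=[s.sample_id for s in cropped],
        groups={t: list(m) for t, m in cropped.groups.items()},
    )


def project(r: PCAResult, s: Spectrum) -> np.ndarray:
    """Score coordinates of a (held-out) spectrum in an existing PCA model."""
    sub = crop_region(s, r.region[0], r.region[1])
    if sub.wavenumbers.shape != r.wavenumbers.shape or not np.allclose(
        sub.wavenumbers, r.wavenumbers
    ):
        raise ValueError(
            f"spectrum {s.sample_id!r} is not on the PCA model grid; resample first"
        )
    return (sub.intensities - r.mean_spectrum) @ r.loadings.T


def group_centroids(
    r: PCAResult, groups: Mapping[str, list[str]] | None = None
) -> dict:
    """Per-treatment centroids and dispersions in score space.

    Returns ``{"centroids": {label: (k,) mean}, "spread": {label: (k,)
    per-axis SD}, "distances": {(label_a, label_b): euclidean centroid
    distance}}``. Single-member groups get zero spread.
    """
    groups = dict(groups) if groups is not None else r.groups
    index = {sid: i for i, sid in enumerate(r.sample_ids)}
    centroids: dict[str, np.ndarray] = {}
    spread: dict[str, np.ndarray] = {}
    for label, members in groups.items():
        if not members:
            raise ValueError(f"group {label!r} is empty")
        try:
            rows = np.array([index[sid] for sid in members])
        except KeyError as e:
            raise ValueError(f"sample {e.args[0]!r} not in the PCA model") from None
        pts = r.scores[rows]
        centroids[label] = pts.mean(axis=0)
        spread[label] = (
            pts.std(axis=0, ddof=1) if len(members) > 1
            else np.zeros(r.n_components)
        )
    labels = sorted(centroids)
    distances = {
        (a, b): float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }
    return {"centroids": centroids, "spread": spread, "distances": distances}
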