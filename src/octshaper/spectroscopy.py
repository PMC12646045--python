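"""Spectroscopic FFOCT: Mie backscattering, constant-lc spectra, particle spectra, PCA.

The spectroscopic measurement acquires tomograms at a series of center
wavelengths while holding the temporal coherence length constant (so the
probed volume does not change), segments particles in the amplitude
images, extracts each particle's amplitude-versus-wavelength spectrum, and
separates single-particle signatures from aggregate contamination with a
principal-component filter.  The expected signatures come from the exact
Mie series for spherical scatterers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import ndimage
from sklearn.decomposition import PCA

from octshaper.source import (
    CalibrationTable,
    Spectrum,
    bandwidth_for_coherence_length,
)
from octshaper.sequences import TargetSpectrum

__all__ = [
    "MieParams",
    "ParticleSpectra",
    "constant_lc_family",
    "extract_particle_spectra",
    "mie_backscatter",
    "mie_coefficients",
    "mie_efficiencies",
    "pca_filter_spectra",
    "segment_particles",
]

X_MAX = 500.0

# Polystyrene bead in agar/water, the default spectroscopy phantom
DEFAULT_PARTICLE_INDEX = 1.59
DEFAULT_MEDIUM_INDEX = 1.34
SILICA_INDEX = 1.45


@dataclass(frozen=True)
class MieParams:
    """Sphere and medium parameters for a Mie backscattering spectrum."""

    diameter: float  # nm
    particle_index: float | NDArray  # scalar or one value per wavelength
    medium_index: float
    wavelengths: NDArray[np.float64]  # nm, vacuum

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if np.any(np.asarray(self.particle_index) < 1) or self.medium_index < 1:
            raise ValueError("refractive indices must be >= 1")
        if np.any(lam <= 0):
            raise ValueError("wavelengths must be positive")
        object.__setattr__(self, "wavelengths", lam)


@dataclass(frozen=True)
class ParticleSpectra:
    """Per-particle amplitude spectra: ``matrix[p, w]`` at ``wavelengths[w]``."""

    matrix: NDArray[np.float64]
    wavelengths: NDArray[np.float64]
    particle_centroids: NDArray[np.float64]  # (P, 2) pixel coordinates

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        lam = np.asarray(self.wavelengths, dtype=float)
        c = np.asarray(self.particle_centroids, dtype=float)
        if m.ndim != 2 or m.shape[1] != lam.size:
            raise ValueError("matrix must be particles x wavelengths")
        if np.any(m < 0):
            raise ValueError("spectra must be non-negative")
        if c.shape != (m.shape[0], 2):
            raise ValueError("one (row, col) centroid per particle")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "particle_centroids", c)

    @property
    def n_particles(self) -> int:
        return self.matrix.shape[0]


def _n_terms(x: float) -> int:
    """Wiscombe series-truncation order."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(x: float, m: float) -> tuple[NDArray, NDArray]:
    """Mie scattering coefficients a_n, b_n (n = 1..n_max) for real index ratio m.

    Logarithmic-derivative route: D_n(mx) by downward recurrence started
    well above the truncation order, Riccati-Bessel functions psi_n and
    xi_n = psi_n - i*chi_n by upward recurrence, then

    ``a_n = [(D_n/m + n/x) psi_n - psi_{n-1}] / [(D_n/m + n/x) xi_n - xi_{n-1}]``
    ``b_n = [(m D_n + n/x) psi_n - psi_{n-1}] / [(m D_n + n/x) xi_n - xi_{n-1}]``
    """
    if not 0 < x < X_MAX:
        raise ValueError(f"size parameter x must lie in (0, {X_MAX:g})")
    nmax = _n_terms(x)
    mx = m * x
    nmx = max(nmax, int(np.ceil(abs(mx)))) + 16
    d = np.zeros(nmx + 1)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    dn = d[1 : nmax + 1]

    n_idx = np.arange(1, nmax + 1)
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    for n in range(1, nmax + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - (psi[n - 2] if n >= 2 else psi_m1)
        chi[n] = (2 * n - 1) / x * chi[n - 1] - (chi[n - 2] if n >= 2 else chi_m1)
    xi = psi - 1j * chi

    fa = dn / m + n_idx / x
    fb = dn * m + n_idx / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return a, b


def mie_efficiencies(x: float, m: float) -> tuple[float, float, float]:
    """(Q_ext, Q_sca, Q_back) for a sphere of size parameter x and index ratio m.

    ``Q_back = (1/x**2) |sum_n (2n+1)(-1)**n (a_n - b_n)|**2``.
    """
    if m == 1.0:
        return 0.0, 0.0, 0.0
    a, b = mie_coefficients(x, m)
    n = np.arange(1, a.size + 1)
    w = 2 * n + 1
    qext = 2.0 / x**2 * np.sum(w * (a + b).real)
    qsca = 2.0 / x**2 * np.sum(w * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qback = 1.0 / x**2 * np.abs(np.sum(w * (-1.0) ** n * (a - b))) ** 2
    return float(qext), float(qsca), float(qback)


def mie_backscatter(params: MieParams) -> Spectrum:
    """Backscattering efficiency Q_back versus wavelength for a sphere.

    The size parameter uses the wavelength in the medium:
    ``x = pi d n_medium / lambda``; the relative index is
    ``m = n_particle / n_medium``.  ``m = 1`` returns a zero spectrum with
    a warning (index-matched particle).
    """
    lam = params.wavelengths
    order = np.argsort(lam)
    lam_sorted = lam[order]
    m_arr = np.broadcast_to(
        np.asarray(params.particle_index, dtype=float) / params.medium_index, lam.shape
    )[order]
    if np.allclose(m_arr, 1.0):
        warnings.warn("index-matched sphere: zero backscattering", stacklevel=2)
        return Spectrum(lam_sorted, np.zeros_like(lam_sorted), "wavelength")
    x = np.pi * params.diameter * params.medium_index / lam_sorted
    qback = np.array(
        [mie_efficiencies(float(xi), float(mi))[2] for xi, mi in zip(x, m_arr)]
    )
    return Spectrum(lam_sorted, qback, "wavelength")


def constant_lc_family(
    centers: ArrayLike, lc: float, table: CalibrationTable | None = None
) -> list[TargetSpectrum]:
    """Gaussian targets at several centers sharing one coherence length.

    Each member gets ``dlambda_i = lambda_i**2 / (2 lc)`` so
    ``coherence_length(lambda_i, dlambda_i) == lc`` identically; the fringe
    envelope (hence the probed axial volume) is the same for every member.
    A warning is raised when a member's bandwidth falls below the
    instantaneous linewidth of the provided calibration.
    """
    if lc <= 0:
        raise ValueError("coherence length must be positive")
    targets = []
    for c in np.atleast_1d(np.asarray(centers, dtype=float)):
        dl = bandwidth_for_coherence_length(float(c), lc)
        if table is not None and dl < float(table.linewidth_at(c)):
            warnings.warn(
                f"requested bandwidth {dl:.2f} nm at {c:.0f} nm is below the "
                "instantaneous linewidth; shaping cannot narrow the line",
                stacklevel=2,
            )
        targets.append(
            TargetSpectrum(shape="gaussian", center_wavelength=float(c), fwhm=dl)
        )
    return targets


def segment_particles(
    image: ArrayLike,
    threshold_sigma: float = 3.0,
    min_area: int = 4,
    max_area: int | float = np.inf,
) -> list[NDArray[np.bool_]]:
    """Threshold/area blob segmentation of a 2-D amplitude image.

    Pixels above ``mean + threshold_sigma * std`` are grouped into
    8-connected components, filtered by area, and returned as boolean
    masks labeled deterministically in raster order.  Two blobs that touch
    above threshold merge into one component.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise ValueError("need a 2-D non-negative image")
    thresh = img.mean() + threshold_sigma * img.std()
    labels, n = ndimage.label(img > thresh, structure=np.ones((3, 3), dtype=int))
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if min_area <= mask.sum() <= max_area:
            masks.append(mask)
    return masks


def extract_particle_spectra(
    stack: ArrayLike, masks: list[NDArray[np.bool_]], wavelengths: ArrayLike
) -> ParticleSpectra:
    """Per-particle maximum amplitude versus wavelength.

    ``stack`` is wavelength-indexed, shape (n_wavelengths, H, W); entry
    (p, w) is the maximum amplitude inside mask p at wavelength w.  An
    empty mask yields a row of zeros with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    lam = np.asarray(wavelengths, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != lam.size:
        raise ValueError("stack must be (n_wavelengths, H, W) matching wavelengths")
    matrix = np.zeros((len(masks), lam.size))
    centroids = np.zeros((len(masks), 2))
    for p, mask in enumerate(masks):
        if mask.shape != stack.shape[1:]:
            raise ValueError("mask shape must match the image shape")
        if not mask.any():
            warnings.warn(f"mask {p} is empty; spectrum set to zero", stacklevel=2)
            continue
        matrix[p] = stack[:, mask].max(axis=1)
        rows, cols = np.nonzero(mask)
        centroids[p] = rows.mean(), cols.mean()
    return ParticleSpectra(matrix=matrix, wavelengths=lam, particle_centroids=centroids)


def pca_filter_spectra(
    spectra: ParticleSpectra, n_components: int = 3, center: bool = True
) -> tuple[ParticleSpectra, NDArray[np.float64]]:
    """Project spectra onto their first principal components.

    Returns the filtered spectra (mean + weighted sum of the first
    ``n_components`` components per particle, clipped at zero) and the
    per-component explained-variance fractions (non-increasing, sum <= 1).
    ``center=False`` reproduces the uncentered variant.
    """
    x = spectra.matrix
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0) if center else x))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds the data rank {rank}")
    if spectra.n_particles < n_components + 1:
        raise ValueError("need at least n_components + 1 particles")
    if center:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(x)
        recon = pca.inverse_transform(scores)
        fractions = pca.explained_variance_ratio_
    else:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components]
        fractions = s**2 / np.sum(s**2)
        fractions = fractions[:n_components]
    filtered = replace(spectra, matrix=np.clip(recon, 0.0, None))
    return filtered, np.asarray(fractions, dtype=float)
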