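"""Tunable-source model: AOTF calibration, instantaneous line, coherence, speckle.

The source is a supercontinuum laser filtered by an acousto-optic tunable
filter (AOTF).  An analog control voltage sets the acoustic frequency and
thereby the transmitted center wavelength; a calibration table maps voltage
to wavelength together with the wavelength-dependent instantaneous
linewidth (FWHM) and relative source efficiency (spectral irradiance at the
sample plane, peak-normalized).  Light is delivered through a long
multimode fiber whose modal dispersion and active shaking decorrelate the
spatial modes, which sets the residual speckle contrast of the
illumination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CalibrationRangeError",
    "CalibrationTable",
    "FiberSpec",
    "SpectralLine",
    "Spectrum",
    "coherence_length",
    "default_calibration",
    "fiber_mode_count",
    "instantaneous_spectrum",
    "speckle_contrast",
    "voltage_for_wavelength",
    "wavelength_for_voltage",
]

TWO_PI = 2.0 * np.pi
# FWHM of a Gaussian = GAUSS_FWHM * sigma
GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class CalibrationRangeError(ValueError):
    """Requested voltage or wavelength lies outside the calibrated range."""


@dataclass(frozen=True)
class Spectrum:
    """Sampled spectral density on a wavelength (nm) or wavenumber (rad/nm) grid.

    ``density`` is a non-negative spectral density *per grid unit*, so the
    wavelength/wavenumber conversion applies the Jacobian |dk/dlambda| =
    2*pi/lambda**2 and preserves integrated power.
    """

    grid: NDArray[np.float64]
    density: NDArray[np.float64]
    grid_kind: Literal["wavelength", "wavenumber"] = "wavelength"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.shape != density.shape:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if grid.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(density < 0):
            raise ValueError("spectral density must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)

    @property
    def integrated_power(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))

    def to_wavenumber(self) -> "Spectrum":
        """Return the same spectrum on a k = 2*pi/lambda grid (power preserved)."""
        if self.grid_kind == "wavenumber":
            return self
        k = TWO_PI / self.grid[::-1]
        # S_k(k) = S_lambda(lambda) * lambda^2 / (2 pi)
        dens = self.density[::-1] * self.grid[::-1] ** 2 / TWO_PI
        return Spectrum(k, dens, "wavenumber")

    def to_wavelength(self) -> "Spectrum":
        if self.grid_kind == "wavelength":
            return self
        lam = TWO_PI / self.grid[::-1]
        dens = self.density[::-1] * self.grid[::-1] ** 2 / TWO_PI
        return Spectrum(lam, dens, "wavelength")

    def normalized(self) -> "Spectrum":
        """Unit integrated power (same grid)."""
        p = self.integrated_power
        if p <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return replace(self, density=self.density / p)

    def peak_normalized(self) -> "Spectrum":
        m = float(self.density.max())
        if m <= 0:
            raise ValueError("cannot peak-normalize an all-zero spectrum")
        return replace(self, density=self.density / m)


@dataclass(frozen=True)
class SpectralLine:
    """One instantaneous AOTF line: Gaussian of given center, FWHM and peak density."""

    center_wavelength: float  # nm
    fwhm: float  # nm
    peak_density: float = 1.0  # relative irradiance

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.peak_density < 0:
            raise ValueError("peak_density must be non-negative")


@dataclass(frozen=True)
class FiberSpec:
    """Step-index multimode delivery fiber."""

    core_diameter: float = 200.0  # um
    numerical_aperture: float = 0.39
    length: float = 100.0  # m

    def __post_init__(self) -> None:
        if min(self.core_diameter, self.numerical_aperture, self.length) <= 0:
            raise ValueError("all fiber parameters must be positive")


@dataclass(frozen=True)
class CalibrationTable:
    """Monotone voltage <-> wavelength calibration with linewidth and efficiency.

    ``wavelength_nodes`` must be strictly monotone in ``voltage_nodes``
    (the physical AOTF curve is monotone decreasing; either sign is
    accepted).  Interpolation between nodes is monotone piecewise cubic
    (PCHIP) for the wavelength, which cannot overshoot and therefore stays
    invertible; linewidth and efficiency are interpolated linearly in
    wavelength.
    """

    voltage_nodes: NDArray[np.float64]
    wavelength_nodes: NDArray[np.float64]
    linewidth_nodes: NDArray[np.float64]
    efficiency_nodes: NDArray[np.float64]
    _fwd: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_nodes, dtype=float)
        lam = np.asarray(self.wavelength_nodes, dtype=float)
        lw = np.asarray(self.linewidth_nodes, dtype=float)
        eff = np.asarray(self.efficiency_nodes, dtype=float)
        if not (v.shape == lam.shape == lw.shape == eff.shape) or v.ndim != 1:
            raise ValueError("all node arrays must be 1-D and of equal length")
        if v.size < 2:
            raise ValueError("need at least two calibration nodes")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltage nodes must be strictly ascending")
        dlam = np.diff(lam)
        if not (np.all(dlam > 0) or np.all(dlam < 0)):
            raise ValueError("wavelength must be strictly monotone in voltage")
        if np.any(lw <= 0):
            raise ValueError("all linewidths must be positive")
        if np.any(eff < 0):
            raise ValueError("efficiencies must be non-negative")
        for name, arr in (
            ("voltage_nodes", v),
            ("wavelength_nodes", lam),
            ("linewidth_nodes", lw),
            ("efficiency_nodes", eff),
        ):
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "_fwd", PchipInterpolator(v, lam, extrapolate=False))

    # -- ranges ---------------------------------------------------------
    @property
    def voltage_range(self) -> tuple[float, float]:
        return float(self.voltage_nodes[0]), float(self.voltage_nodes[-1])

    @property
    def wavelength_range(self) -> tuple[float, float]:
        lo = float(min(self.wavelength_nodes[0], self.wavelength_nodes[-1]))
        hi = float(max(self.wavelength_nodes[0], self.wavelength_nodes[-1]))
        return lo, hi

    def _wavelength_sorted(self) -> tuple[NDArray, NDArray, NDArray]:
        order = np.argsort(self.wavelength_nodes)
        return (
            self.wavelength_nodes[order],
            self.linewidth_nodes[order],
            self.efficiency_nodes[order],
        )

    def linewidth_at(self, lam: ArrayLike) -> NDArray[np.float64]:
        """Instantaneous FWHM (nm) at wavelength ``lam``; linear between nodes."""
        lam_s, lw_s, _ = self._wavelength_sorted()
        self._check_wavelength(lam)
        return np.interp(np.asarray(lam, dtype=float), lam_s, lw_s)

    def efficiency_at(self, lam: ArrayLike) -> NDArray[np.float64]:
        """Relative source efficiency at wavelength ``lam``; linear between nodes."""
        lam_s, _, eff_s = self._wavelength_sorted()
        self._check_wavelength(lam)
        return np.interp(np.asarray(lam, dtype=float), lam_s, eff_s)

    def _check_wavelength(self, lam: ArrayLike) -> None:
        lam = np.asarray(lam, dtype=float)
        lo, hi = self.wavelength_range
        if np.any(lam < lo - 1e-9) or np.any(lam > hi + 1e-9):
            raise CalibrationRangeError(
                f"wavelength outside calibrated range [{lo:g}, {hi:g}] nm"
            )

    def _check_voltage(self, v: ArrayLike) -> None:
        v = np.asarray(v, dtype=float)
        lo, hi = self.voltage_range
        if np.any(v < lo - 1e-12) or np.any(v > hi + 1e-12):
            raise CalibrationRangeError(
                f"voltage outside calibrated range [{lo:g}, {hi:g}] V"
            )


def wavelength_for_voltage(table: CalibrationTable, v: ArrayLike) -> NDArray | float:
    """Center wavelength (nm) produced by control voltage ``v``.

    Monotone piecewise-cubic interpolation through the calibration nodes;
    exact at the nodes.
    """
    table._check_voltage(v)
    lo, hi = table.voltage_range
    out = table._fwd(np.clip(np.asarray(v, dtype=float), lo, hi))
    return float(out) if np.isscalar(v) or np.asarray(v).ndim == 0 else out


def voltage_for_wavelength(table: CalibrationTable, lam: ArrayLike) -> NDArray | float:
    """Control voltage producing center wavelength ``lam`` (nm).

    Numerically exact inverse of :func:`wavelength_for_voltage`: roots of
    the forward monotone cubic are solved per polynomial piece, so the
    round trip closes to machine precision.
    """
    table._check_wavelength(lam)
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    lam_lo, lam_hi = table.wavelength_range
    lam_arr = np.clip(lam_arr, lam_lo, lam_hi)
    volts = np.empty_like(lam_arr)
    for i, target in enumerate(lam_arr):
        roots = table._fwd.solve(target, extrapolate=False)
        if roots.size == 0:  # endpoint rounding
            node = np.argmin(np.abs(table.wavelength_nodes - target))
            volts[i] = table.voltage_nodes[node]
        else:
            volts[i] = roots[0]
    return float(volts[0]) if np.isscalar(lam) or np.asarray(lam).ndim == 0 else volts


def instantaneous_spectrum(
    table: CalibrationTable, center: float, grid: ArrayLike
) -> Spectrum:
    """Instantaneous AOTF line at a fixed voltage, sampled on ``grid`` (nm).

    A Gaussian of FWHM equal to the interpolated instantaneous linewidth at
    ``center`` and peak density equal to the interpolated source
    efficiency.  On a grid spanning at least +-2 FWHM the integral equals
    ``efficiency * fwhm * sqrt(pi / (4 ln 2))``.
    """
    grid = np.asarray(grid, dtype=float)
    fwhm_nm = float(table.linewidth_at(center))
    eff = float(table.efficiency_at(center))
    if grid[0] > center - 2 * fwhm_nm or grid[-1] < center + 2 * fwhm_nm:
        warnings.warn(
            "grid does not cover +-2 FWHM around the line center; "
            "the integrated power will be truncated",
            stacklevel=2,
        )
    sigma = fwhm_nm / GAUSS_FWHM
    density = eff * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, density, "wavelength")


def line_spectrum(line: SpectralLine, grid: ArrayLike) -> Spectrum:
    """Sample a :class:`SpectralLine` on a wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    sigma = line.fwhm / GAUSS_FWHM
    density = line.peak_density * np.exp(
        -0.5 * ((grid - line.center_wavelength) / sigma) ** 2
    )
    return Spectrum(grid, density, "wavelength")


def coherence_length(
    center: float,
    fwhm: float,
    convention: Literal["half_bandwidth", "gaussian_envelope"] = "half_bandwidth",
) -> float:
    """Temporal coherence length (um) of a line of given center and FWHM (nm).

    Default convention ``half_bandwidth``: ``lc = lambda0**2 / (2 * dlambda)``.
    The ``gaussian_envelope`` alternative returns the FWHM in optical path
    of the fringe envelope of a Gaussian spectrum,
    ``(4 ln 2 / pi) * lambda0**2 / dlambda``; it is provided as a
    documented option, not the default.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    base_nm = center**2 / fwhm
    if convention == "half_bandwidth":
        return base_nm / 2.0 / 1000.0
    if convention == "gaussian_envelope":
        return (4.0 * np.log(2.0) / np.pi) * base_nm / 1000.0
    raise ValueError(f"unknown convention {convention!r}")


def bandwidth_for_coherence_length(center: float, lc_um: float) -> float:
    """FWHM (nm) giving coherence length ``lc_um`` at ``center`` (half-bandwidth rule)."""
    if lc_um <= 0:
        raise ValueError("coherence length must be positive")
    return center**2 / (2.0 * lc_um * 1000.0)


def fiber_mode_count(fiber: FiberSpec, lam: float) -> float:
    """Number of guided spatial modes per polarization at wavelength ``lam`` (nm).

    Step-index estimate M = V**2 / 2 with V = pi * d * NA / lambda.  The
    wavelength is an explicit argument: the mode count scales as
    1/lambda**2 and quoting it without a wavelength is meaningless.
    """
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    v_number = np.pi * fiber.core_diameter * 1000.0 * fiber.numerical_aperture / lam
    return float(v_number**2 / 2.0)


def speckle_contrast(
    n_modes: int,
    n_averages: int,
    image_shape: tuple[int, int] = (256, 256),
    seed: int | None = None,
) -> tuple[NDArray[np.float64], float]:
    """Simulate a multimode speckle illumination and return (image, contrast).

    Each spatial mode travels with a differential delay exceeding the
    temporal coherence length, so modes superpose in intensity, not in
    field: every mode contributes an independent fully developed speckle
    pattern (squared magnitude of a circular complex Gaussian field per
    pixel), and active mode mixing averages ``n_averages`` further
    independent realizations within one exposure.  The contrast std/mean
    therefore follows 1/sqrt(n_modes * n_averages); a single static mode
    gives the fully developed value of 1.
    """
    if n_modes < 1 or n_averages < 1:
        raise ValueError("n_modes and n_averages must be >= 1")
    rng = np.random.default_rng(seed)
    total = int(n_modes) * int(n_averages)
    image = np.zeros(image_shape, dtype=float)
    chunk = max(1, min(total, 64))
    done = 0
    while done < total:
        m = min(chunk, total - done)
        re = rng.standard_normal((m, *image_shape))
        im = rng.standard_normal((m, *image_shape))
        image += 0.5 * (re**2 + im**2).sum(axis=0)
        done += m
    contrast = float(image.std() / image.mean())
    return image, contrast


def default_calibration(n_nodes: int = 24) -> CalibrationTable:
    """Shipped synthetic calibration emulating the characterized AOTF.

    Linear voltage -> wavelength over the filter's 575-1040 nm bandwidth
    (0 V -> 1040 nm down to 10 V -> 575 nm, monotone decreasing like the
    measured curve), instantaneous linewidth rising linearly from 2.5 nm at
    575 nm to 9 nm at 1040 nm, and a smooth efficiency bump peaking near
    800 nm where the delivered spectral irradiance is brightest.
    """
    volts = np.linspace(0.0, 10.0, n_nodes)
    lam = 1040.0 + (575.0 - 1040.0) * volts / 10.0
    linewidth = 2.5 + (lam - 575.0) / (1040.0 - 575.0) * (9.0 - 2.5)
    efficiency = 0.25 + 0.75 * np.exp(-(((lam - 800.0) / 150.0) ** 2))
    efficiency = efficiency / efficiency.max()
    return CalibrationTable(volts, lam, linewidth, efficiency)
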