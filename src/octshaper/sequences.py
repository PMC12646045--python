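"""Turn target spectra into AOTF schedules.

Two operating modes are supported:

* **Time-domain shaping** — inside a single camera exposure the control
  voltage visits many wavelengths, each held for a dwell time proportional
  to the target spectral density divided by the source efficiency, so the
  time-integrated spectrum reproduces the target shape.
* **Swept-source mode** — one constant wavelength per camera frame,
  uniformly spaced in wavenumber k = 2*pi/lambda, with per-frame exposure
  weights (TTL duty cycle) that equalize the effective spectrum across the
  band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

from octshaper.source import (
    GAUSS_FWHM,
    TWO_PI,
    CalibrationTable,
    Spectrum,
    voltage_for_wavelength,
    wavelength_for_voltage,
)

__all__ = [
    "SweepPlan",
    "TargetSpectrum",
    "VoltageSequence",
    "apply_timing_delays",
    "design_exposure_shaping",
    "design_k_linear_sweep",
    "design_td_sequence",
    "predict_integrated_spectrum",
]

# Half-max half-width of the Blackman window in units of its half-support:
# solve 0.42 + 0.5*cos(phi) + 0.08*cos(2*phi) = 0.5 for phi, u0 = phi/pi.
_BLACKMAN_COS = (-0.5 + np.sqrt(0.25 + 4 * 0.16 * 0.16)) / (2 * 0.16)
BLACKMAN_FWHM_FRACTION = float(np.arccos(_BLACKMAN_COS) / np.pi)  # ~0.40541

#: Support width as a multiple of FWHM for the truncated-Gaussian target.
GAUSSIAN_SUPPORT_FACTOR = 1.0 / 0.6

MIN_DWELL_US = 3.0  # AOTF crystal response time
RF_DELAY_US = 50.0  # constant RF-driver latency
ACOUSTIC_DELAY_US = 3.0  # ultrasound propagation across the crystal


@dataclass(frozen=True)
class TargetSpectrum:
    """Parametric or tabulated spectral-density target (peak-normalized).

    Parametric shapes are defined so their density FWHM equals ``fwhm``:
    the rectangle has width ``fwhm``; the Gaussian is truncated at a total
    support of ``fwhm * GAUSSIAN_SUPPORT_FACTOR``; the Blackman window
    (coefficients 0.42, 0.5, 0.08) spans ``fwhm / BLACKMAN_FWHM_FRACTION``.
    """

    shape: Literal["rectangular", "gaussian", "blackman", "tabulated"]
    center_wavelength: float | None = None  # nm
    fwhm: float | None = None  # nm
    table: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.shape == "tabulated":
            if self.table is None:
                raise ValueError("tabulated target requires a Spectrum table")
        else:
            if self.center_wavelength is None or self.fwhm is None:
                raise ValueError(f"{self.shape} target requires center and fwhm")
            if self.fwhm <= 0:
                raise ValueError("fwhm must be positive")

    @property
    def support(self) -> tuple[float, float]:
        """Wavelength interval (nm) outside which the target density is zero."""
        if self.shape == "tabulated":
            tab = self.table.to_wavelength()
            nz = np.nonzero(tab.density > 1e-12 * tab.density.max())[0]
            return float(tab.grid[nz[0]]), float(tab.grid[nz[-1]])
        c, f = self.center_wavelength, self.fwhm
        if self.shape == "rectangular":
            half = f / 2.0
        elif self.shape == "gaussian":
            half = f * GAUSSIAN_SUPPORT_FACTOR / 2.0
        else:  # blackman
            half = f / BLACKMAN_FWHM_FRACTION / 2.0
        return c - half, c + half

    def density(self, grid: ArrayLike) -> NDArray[np.float64]:
        """Sample the target density (peak 1) on a wavelength grid (nm)."""
        grid = np.asarray(grid, dtype=float)
        if self.shape == "tabulated":
            tab = self.table.to_wavelength().peak_normalized()
            return np.interp(grid, tab.grid, tab.density, left=0.0, right=0.0)
        lo, hi = self.support
        inside = (grid >= lo) & (grid <= hi)
        out = np.zeros_like(grid)
        if self.shape == "rectangular":
            out[inside] = 1.0
        elif self.shape == "gaussian":
            sigma = self.fwhm / GAUSS_FWHM
            out[inside] = np.exp(
                -0.5 * ((grid[inside] - self.center_wavelength) / sigma) ** 2
            )
        else:  # blackman
            u = (grid[inside] - self.center_wavelength) / ((hi - lo) / 2.0)
            out[inside] = 0.42 + 0.5 * np.cos(np.pi * u) + 0.08 * np.cos(2 * np.pi * u)
            np.clip(out, 0.0, None, out=out)
        return out

    def as_spectrum(self, n: int = 2001, pad: float = 0.25) -> Spectrum:
        """Render the target on a dense wavelength grid (support padded by ``pad``)."""
        lo, hi = self.support
        span = hi - lo
        grid = np.linspace(lo - pad * span, hi + pad * span, n)
        return Spectrum(grid, self.density(grid), "wavelength")


@dataclass(frozen=True)
class VoltageSequence:
    """Timed AOTF schedule inside one camera exposure (time-domain mode).

    ``timeline_offset`` is the time of the first command relative to the
    start of the camera exposure; delay compensation makes it negative so
    the optical output aligns with the exposure window.
    """

    voltages: NDArray[np.float64]  # V, one per step
    dwells: NDArray[np.float64]  # us, one per step
    exposure: float  # us
    rf_delay: float = RF_DELAY_US  # us
    acoustic_delay: float = ACOUSTIC_DELAY_US  # us
    timeline_offset: float = 0.0  # us
    min_dwell: float = MIN_DWELL_US  # us
    wavelengths: NDArray[np.float64] | None = None  # nm, convenience copy

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        d = np.asarray(self.dwells, dtype=float)
        if v.shape != d.shape or v.ndim != 1:
            raise ValueError("voltages and dwells must be 1-D arrays of equal length")
        if np.any(d < 0):
            raise ValueError("dwell times must be non-negative")
        if abs(d.sum() - self.exposure) > self.min_dwell + 1e-9:
            raise ValueError(
                "total dwell must equal the exposure within one dwell quantum"
            )
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "dwells", d)
        if self.wavelengths is not None:
            object.__setattr__(
                self, "wavelengths", np.asarray(self.wavelengths, dtype=float)
            )

    @property
    def n_steps(self) -> int:
        return self.voltages.size

    @property
    def start_times(self) -> NDArray[np.float64]:
        """Command start times (us) relative to the camera exposure start."""
        return self.timeline_offset + np.concatenate(
            ([0.0], np.cumsum(self.dwells[:-1]))
        )

    def to_csv(self, path: str | Path, table: CalibrationTable | None = None) -> None:
        """Write ``t_start_us,voltage_V,wavelength_nm,dwell_us`` plus a JSON sidecar."""
        import pandas as pd

        path = Path(path)
        lam = self.wavelengths
        if lam is None:
            lam = (
                wavelength_for_voltage(table, self.voltages)
                if table is not None
                else np.full_like(self.voltages, np.nan)
            )
        pd.DataFrame(
            {
                "t_start_us": self.start_times,
                "voltage_V": self.voltages,
                "wavelength_nm": lam,
                "dwell_us": self.dwells,
            }
        ).to_csv(path, index=False, float_format="%.9g")
        sidecar = {
            "exposure_us": self.exposure,
            "rf_delay_us": self.rf_delay,
            "acoustic_delay_us": self.acoustic_delay,
            "timeline_offset_us": self.timeline_offset,
            "min_dwell_us": self.min_dwell,
            "n_steps": int(self.n_steps),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


@dataclass(frozen=True)
class SweepPlan:
    """Per-frame wavelengths of a k-linear sweep with exposure weights.

    Frames are ordered by ascending wavenumber (descending wavelength);
    uniform k spacing is asserted at construction.
    """

    wavelengths: NDArray[np.float64]  # nm
    wavenumbers: NDArray[np.float64]  # rad/nm
    exposure_weights: NDArray[np.float64]  # dimensionless, max 1
    frame_period: float = 10_000.0  # us (100 fps)

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        k = np.asarray(self.wavenumbers, dtype=float)
        w = np.asarray(self.exposure_weights, dtype=float)
        if not (lam.shape == k.shape == w.shape) or lam.ndim != 1 or lam.size < 2:
            raise ValueError("plan arrays must be 1-D, equal length >= 2")
        dk = np.diff(k)
        if np.any(dk <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if np.max(np.abs(dk - dk[0])) > 1e-12 * abs(dk[0]):
            raise ValueError("wavenumbers must be uniformly spaced (k-linear sweep)")
        if np.any(w <= 0):
            raise ValueError("exposure weights must be positive")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "wavenumbers", k)
        object.__setattr__(self, "exposure_weights", w)

    @property
    def n_frames(self) -> int:
        return self.wavelengths.size

    @property
    def dk(self) -> float:
        """Wavenumber increment between frames (rad/nm)."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "wavelength_nm": self.wavelengths,
                "wavenumber_rad_per_nm": self.wavenumbers,
                "exposure_weight": self.exposure_weights,
            }
        ).to_csv(path, index=False, float_format="%.12g")


def _quantize_largest_remainder(
    raw: NDArray[np.float64], total_units: int
) -> NDArray[np.int64]:
    """Integer apportionment of ``total_units`` proportional to ``raw``."""
    share = raw / raw.sum() * total_units
    base = np.floor(share).astype(np.int64)
    missing = total_units - int(base.sum())
    if missing > 0:
        order = np.argsort(-(share - base), kind="stable")
        base[order[:missing]] += 1
    return base


def _richardson_lucy_1d(
    target: NDArray, kernel: NDArray, iterations: int
) -> NDArray:
    """Non-negative 1-D deconvolution of ``target`` by a normalized ``kernel``."""
    kernel = kernel / kernel.sum()
    mirror = kernel[::-1]
    estimate = np.clip(target, 1e-12, None)
    for _ in range(iterations):
        blurred = np.convolve(estimate, kernel, mode="same")
        ratio = target / np.clip(blurred, 1e-12, None)
        estimate = estimate * np.convolve(ratio, mirror, mode="same")
    return estimate


def design_td_sequence(
    target: TargetSpectrum,
    table: CalibrationTable,
    exposure: float,
    n_steps: int = 64,
    min_dwell: float = MIN_DWELL_US,
    precompensate_linewidth: bool = False,
    rl_iterations: int = 40,
) -> VoltageSequence:
    """Design a voltage/dwell schedule whose time-integrated spectrum is ``target``.

    ``n_steps`` wavelengths are placed uniformly across the target support
    and each is held for a dwell proportional to
    ``S_target(lambda) / efficiency(lambda)``, so the weaker band edges get
    proportionally more time.  Dwells are quantized to ``min_dwell``
    multiples with largest-remainder redistribution, preserving the total
    exposure to within one quantum.

    ``precompensate_linewidth=True`` additionally Richardson-Lucy
    deconvolves the target by the instantaneous Gaussian line before
    computing dwells, sharpening features (e.g. rectangle edges) that the
    finite AOTF linewidth would otherwise blur.  It is off by default: the
    plain proportional-dwell rule already reproduces smooth targets well.
    """
    lo, hi = target.support
    lam_lo, lam_hi = table.wavelength_range
    if lo < lam_lo or hi > lam_hi:
        raise ValueError(
            f"target support [{lo:g}, {hi:g}] nm exceeds the calibrated "
            f"range [{lam_lo:g}, {lam_hi:g}] nm"
        )
    if n_steps * min_dwell > exposure + 1e-9:
        raise ValueError("n_steps * min_dwell exceeds the exposure time")

    lam = np.linspace(lo, hi, n_steps)
    if precompensate_linewidth:
        center = 0.5 * (lo + hi)
        lw = float(table.linewidth_at(center))
        sigma = lw / GAUSS_FWHM
        # pad the deconvolution domain so the support edges are interior
        pad = 5.0 * sigma
        fine = np.linspace(lo - pad, hi + pad, max(2048, 16 * n_steps))
        dx = fine[1] - fine[0]
        half = int(np.ceil(4 * sigma / dx))
        kern = np.exp(-0.5 * ((np.arange(-half, half + 1) * dx) / sigma) ** 2)
        sharp = _richardson_lucy_1d(target.density(fine), kern, rl_iterations)
        dens = np.interp(lam, fine, sharp)
    else:
        dens = target.density(lam)

    eff = np.asarray(table.efficiency_at(lam), dtype=float)
    live = dens > 0
    if np.any(eff[live] <= 0):
        dead = lam[live & (eff <= 0)]
        raise ValueError(
            f"source efficiency is zero inside the target support near "
            f"{dead.min():.1f}-{dead.max():.1f} nm; the target cannot be shaped"
        )

    if target.shape != "tabulated":
        lw_center = float(table.linewidth_at(target.center_wavelength))
        if target.fwhm < lw_center:
            warnings.warn(
                "target FWHM is below the instantaneous linewidth; "
                "time-multiplexed shaping cannot narrow the line",
                stacklevel=2,
            )

    weights = np.zeros_like(dens)
    weights[live] = dens[live] / eff[live]
    total_units = int(round(exposure / min_dwell))
    units = _quantize_largest_remainder(weights, total_units)
    dwells = units * min_dwell

    keep = dwells > 0
    lam, dwells = lam[keep], dwells[keep]
    order = np.argsort(lam)
    lam, dwells = lam[order], dwells[order]
    volts = np.atleast_1d(voltage_for_wavelength(table, lam))
    return VoltageSequence(
        voltages=volts,
        dwells=dwells,
        exposure=total_units * min_dwell,
        min_dwell=min_dwell,
        wavelengths=lam,
    )


def predict_integrated_spectrum(
    seq: VoltageSequence, table: CalibrationTable, grid: ArrayLike
) -> Spectrum:
    """Spectrum a spectrometer would time-integrate over one exposure.

    Sum of the instantaneous Gaussian lines at each step's wavelength,
    weighted by dwell time and source efficiency, normalized to unit peak.
    """
    grid = np.asarray(grid, dtype=float)
    lam = (
        seq.wavelengths
        if seq.wavelengths is not None
        else np.atleast_1d(wavelength_for_voltage(table, seq.voltages))
    )
    lw = np.asarray(table.linewidth_at(lam), dtype=float)
    eff = np.asarray(table.efficiency_at(lam), dtype=float)
    sigma = lw / GAUSS_FWHM
    # (n_steps, n_grid) Gaussian lines, dwell- and efficiency-weighted
    lines = np.exp(-0.5 * ((grid[None, :] - lam[:, None]) / sigma[:, None]) ** 2)
    dens = (seq.dwells[:, None] * eff[:, None] * lines).sum(axis=0)
    peak = dens.max()
    if peak <= 0:
        raise ValueError("predicted spectrum is identically zero")
    return Spectrum(grid, dens / peak, "wavelength")


def design_k_linear_sweep(
    lam_min: float,
    lam_max: float,
    n_frames: int,
    table: CalibrationTable,
    frame_period: float = 10_000.0,
) -> SweepPlan:
    """Sweep plan with ``n_frames`` wavelengths uniformly spaced in k = 2*pi/lambda.

    Endpoints are included: k runs from ``2*pi/lam_max`` to ``2*pi/lam_min``.
    All wavelengths must be resolvable through the calibration table.
    """
    if n_frames < 2:
        raise ValueError("a sweep needs at least 2 frames")
    if lam_min >= lam_max:
        raise ValueError("lam_min must be below lam_max")
    lam_lo, lam_hi = table.wavelength_range
    if lam_min < lam_lo or lam_max > lam_hi:
        raise ValueError(
            f"sweep band [{lam_min:g}, {lam_max:g}] nm exceeds the calibrated "
            f"range [{lam_lo:g}, {lam_hi:g}] nm"
        )
    k = np.linspace(TWO_PI / lam_max, TWO_PI / lam_min, n_frames)
    lam = TWO_PI / k
    voltage_for_wavelength(table, lam)  # raises if unresolvable
    return SweepPlan(
        wavelengths=lam,
        wavenumbers=k,
        exposure_weights=np.ones(n_frames),
        frame_period=frame_period,
    )


def design_exposure_shaping(plan: SweepPlan, table: CalibrationTable) -> SweepPlan:
    """Per-frame exposure weights that flatten the effective spectrum.

    The camera TTL duty cycle overexposes the weak band edges:
    ``weight_n`` is proportional to ``1 / efficiency(lambda_n)`` and
    normalized so the largest weight is 1, making
    ``efficiency * weight`` constant across frames.
    """
    eff = np.asarray(table.efficiency_at(plan.wavelengths), dtype=float)
    if np.any(eff <= 0):
        bad = plan.wavelengths[eff <= 0]
        raise ValueError(
            f"zero source efficiency at {bad.min():.1f}-{bad.max():.1f} nm; "
            "exposure shaping cannot flatten a dead band"
        )
    weights = 1.0 / eff
    weights /= weights.max()
    return replace(plan, exposure_weights=weights)


def apply_timing_delays(seq: VoltageSequence) -> VoltageSequence:
    """Advance the command timeline so the optical output aligns with the exposure.

    The RF driver and the acoustic propagation through the crystal delay
    the optical response by ``rf_delay + acoustic_delay``; the compensated
    command stream therefore starts that long *before* the exposure.
    Idempotent: applying twice shifts only once.
    """
    offset = -(seq.rf_delay + seq.acoustic_delay)
    if seq.timeline_offset == offset:
        return seq
    return replace(seq, timeline_offset=offset)
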