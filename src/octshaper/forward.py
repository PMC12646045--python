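"""FFOCT signal formation on synthetic phantoms.

Time-domain mode: the reference arm is stepped in phase (piezo) and in
length (motorized stage); the camera records the interference of the
sample field with the reference field, the fringe visibility being set by
the illumination spectrum's autocorrelation (Wiener-Khinchin).

Swept-source mode: one narrow line per camera frame, uniformly stepped in
wavenumber; depth structure appears as cosine fringes along k, attenuated
at large optical path difference (OPD) by the finite instantaneous
linewidth (sensitivity roll-off).

Conventions: OPD = 2 * geometric depth * medium index (double pass),
depths in um, wavenumbers in rad/nm (phases use OPD in nm).  All signal
operations accept scalar reflectivities (A-line mode) or 2-D reflectivity
maps (image mode) via broadcasting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from octshaper.source import GAUSS_FWHM, TWO_PI, CalibrationTable, Spectrum
from octshaper.sequences import SweepPlan

__all__ = [
    "KStack",
    "Phantom",
    "PhaseSteppedFrames",
    "Reflector",
    "fringe_envelope",
    "gaussian_line_visibility",
    "simulate_axial_scan",
    "simulate_ss_stack",
    "td_frames",
]

FOUR_PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass(frozen=True)
class Reflector:
    """One discrete reflector: geometric depth (um) and amplitude reflectivity sqrt(R)."""

    depth: float  # um, geometric
    amplitude: float | NDArray = 1.0  # sqrt of intensity reflectivity
    spectral_response_id: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitude reflectivity must be non-negative")


@dataclass(frozen=True)
class Phantom:
    """Reflectors embedded in a homogeneous medium.

    ``spectral_responses`` maps a reflector's ``spectral_response_id`` to a
    callable ``lambda_nm -> amplitude scale`` (e.g. a Mie backscattering
    amplitude); it multiplies the reflector amplitude per wavelength in
    swept-source mode and at the spectrum's power-weighted mean wavelength
    in time-domain mode.
    """

    reflectors: tuple[Reflector, ...]
    medium_index: float = 1.0
    spectral_responses: dict[str, Callable[[float], float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.medium_index < 1.0:
            raise ValueError("medium index must be >= 1")
        object.__setattr__(self, "reflectors", tuple(self.reflectors))

    def opd(self, r: Reflector) -> float:
        """Round-trip optical path (um) of a reflector: 2 * depth * n_medium."""
        return 2.0 * r.depth * self.medium_index

    def _scale(self, r: Reflector, lam_nm: float) -> float:
        if r.spectral_response_id is None:
            return 1.0
        return float(self.spectral_responses[r.spectral_response_id](lam_nm))


@dataclass(frozen=True)
class PhaseSteppedFrames:
    """Intensity frames at the piezo phase steps (2- or 4-phase modulation)."""

    phases: tuple[float, ...]
    intensities: tuple[NDArray | float, ...]
    reference_reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if len(self.phases) not in (2, 4):
            raise ValueError("2- or 4-phase modulation only")
        if len(self.intensities) != len(self.phases):
            raise ValueError("one intensity per phase")
        ph = tuple(float(p) for p in self.phases)
        if any(b <= a for a, b in zip(ph, ph[1:])) or ph[0] < 0 or ph[-1] >= TWO_PI:
            raise ValueError("phases must be strictly increasing within [0, 2*pi)")
        if any(np.any(np.asarray(i) < 0) for i in self.intensities):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "phases", ph)
        object.__setattr__(self, "intensities", tuple(self.intensities))


@dataclass(frozen=True)
class KStack:
    """Swept-source interferogram series along k, with the reference-only series.

    ``reference_frames`` is the same acquisition with the object arm
    blocked (incoherent background); ``gains`` records the per-frame
    ``exposure_weight * efficiency`` factor applied by the simulator so
    reconstruction can divide it out.
    """

    plan: SweepPlan
    frames: NDArray[np.float64]
    reference_frames: NDArray[np.float64]
    gains: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        ref = np.asarray(self.reference_frames, dtype=float)
        if frames.shape != ref.shape:
            raise ValueError("frames and reference_frames must share a shape")
        if frames.shape[0] != self.plan.n_frames:
            raise ValueError("frame count must match the sweep plan")
        if np.any(frames < 0) or np.any(ref < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "reference_frames", ref)
        if self.gains is not None:
            object.__setattr__(self, "gains", np.asarray(self.gains, dtype=float))


def fringe_envelope(spectrum: Spectrum, opd: ArrayLike) -> NDArray | complex:
    """Complex fringe amplitude gamma(OPD) of an illumination spectrum.

    ``gamma(OPD) = integral S(k) exp(i k OPD) dk`` with S normalized to unit
    integrated power in k (so ``|gamma(0)| = 1``); trapezoidal quadrature
    on the spectrum's own wavenumber grid.  ``opd`` in um.
    """
    spec_k = spectrum.to_wavenumber()
    if spec_k.integrated_power <= 0:
        raise ValueError("spectrum has no power")
    spec_k = spec_k.normalized()
    opd_nm = np.asarray(opd, dtype=float) * 1000.0
    scalar = opd_nm.ndim == 0
    flat = np.atleast_1d(opd_nm)
    gamma = np.empty(flat.size, dtype=complex)
    chunk = max(1, 2_000_000 // spec_k.grid.size)  # bound the outer product
    for i in range(0, flat.size, chunk):
        phase = np.multiply.outer(flat[i : i + chunk], spec_k.grid)
        gamma[i : i + chunk] = np.trapezoid(
            spec_k.density * np.exp(1j * phase), spec_k.grid, axis=-1
        )
    return complex(gamma[0]) if scalar else gamma


def gaussian_line_visibility(opd_um: ArrayLike, center_nm: float, fwhm_nm: float) -> NDArray | float:
    """Fringe visibility of a Gaussian line of given FWHM at an OPD (um).

    Closed form of ``|fringe_envelope|`` for a Gaussian spectrum:
    ``exp(-dk_fwhm**2 * OPD**2 / (16 ln 2))`` with
    ``dk_fwhm = 2 pi fwhm / center**2``; strictly decreasing in OPD.
    """
    dk = TWO_PI * fwhm_nm / center_nm**2  # rad/nm
    opd_nm = np.asarray(opd_um, dtype=float) * 1000.0
    out = np.exp(-(dk**2) * opd_nm**2 / (16.0 * np.log(2.0)))
    return float(out) if out.ndim == 0 else out


def _coherent_sum(
    phantom: Phantom,
    spectrum: Spectrum,
    reference_opd: float,
    reference_reflectivity: float,
) -> tuple[NDArray | complex, NDArray | float]:
    """(complex interference amplitude, DC level) for a TD configuration."""
    lam_spec = spectrum.to_wavelength()
    lam_mean = float(
        np.trapezoid(lam_spec.grid * lam_spec.density, lam_spec.grid)
        / max(lam_spec.integrated_power, 1e-300)
    )
    dc = reference_reflectivity
    amp = 0.0
    for r in phantom.reflectors:
        a = np.asarray(r.amplitude, dtype=float) * phantom._scale(r, lam_mean)
        delta = phantom.opd(r) - reference_opd
        gamma = fringe_envelope(spectrum, delta)
        amp = amp + 2.0 * np.sqrt(reference_reflectivity) * a * gamma
        dc = dc + a**2
    return amp, dc


def td_frames(
    phantom: Phantom,
    spectrum: Spectrum,
    reference_opd: float,
    phases: Sequence[float] = FOUR_PHASES,
    reference_reflectivity: float = 1.0,
) -> PhaseSteppedFrames:
    """Phase-stepped TD interference intensities at one reference OPD (um).

    ``I_p = I_dc + sum_r 2 sqrt(R_ref R_r) |gamma(D_r)| cos(arg gamma(D_r) + phi_p)``
    with ``D_r = 2 z_r n_medium - reference_opd``; the DC term collects all
    single-arm intensities.
    """
    amp, dc = _coherent_sum(phantom, spectrum, reference_opd, reference_reflectivity)
    amp = np.asarray(amp, dtype=complex)
    intensities = tuple(
        np.maximum(dc + np.real(amp * np.exp(1j * p)), 0.0) for p in phases
    )
    if np.isscalar(dc) and all(np.ndim(i) == 0 for i in intensities):
        intensities = tuple(float(i) for i in intensities)
    return PhaseSteppedFrames(tuple(phases), intensities, reference_reflectivity)


def simulate_axial_scan(
    phantom: Phantom,
    spectrum: Spectrum,
    opd_grid: ArrayLike,
    reference_reflectivity: float = 1.0,
):
    """Demodulated TD amplitude versus reference-arm OPD (um).

    The 4-phase demodulation of :func:`td_frames` recovers exactly
    ``|sum_r 2 sqrt(R_ref R_r) gamma(D_r)|`` (the coherent reflector sum),
    which is what this scan evaluates at each reference OPD; for a single
    unit mirror it is the fringe envelope ``|gamma|``.  Returns an
    :class:`~octshaper.recon.AxialProfile` on the depth axis
    ``opd_grid / 2``.
    """
    from octshaper.recon import AxialProfile

    opd_grid = np.asarray(opd_grid, dtype=float)
    amps = np.empty(opd_grid.size, dtype=float)
    for i, ref_opd in enumerate(opd_grid):
        amp, _ = _coherent_sum(phantom, spectrum, float(ref_opd), reference_reflectivity)
        amps[i] = float(np.abs(amp)) if np.ndim(amp) == 0 else float(np.abs(amp).mean())
    return AxialProfile(
        depth_grid=opd_grid / 2.0,
        amplitude=amps,
        meta={"kind": "td_axial_scan", "window": "none", "zero_pad": 1},
    )


def simulate_ss_stack(
    phantom: Phantom,
    plan: SweepPlan,
    table: CalibrationTable,
    full_well: float | None = None,
    seed: int | None = None,
    reference_reflectivity: float = 1.0,
    dc_background: float = 0.0,
) -> KStack:
    """Swept-source interferogram stack for a phantom.

    Per frame n at wavelength lambda_n (wavenumber k_n):
    ``frame_n = w_n eta_n [DC + sum_r 2 sqrt(R_ref R_r) V_n(D_r) cos(k_n D_r)]``
    where ``V_n`` is the Gaussian fringe visibility of the instantaneous
    line at lambda_n (sensitivity roll-off) and ``w_n`` the exposure
    weight.  ``reference_frames`` repeats the acquisition with the
    interference term removed (object arm blocked, so sample single-arm
    intensity is absent too).  With ``full_well`` and ``seed`` given, both
    stacks get Poisson shot noise with the intensity scale mapped to
    electrons at ``full_well``; noiseless otherwise.
    """
    lam = plan.wavelengths
    k = plan.wavenumbers
    eta = np.asarray(table.efficiency_at(lam), dtype=float)
    lw = np.asarray(table.linewidth_at(lam), dtype=float)
    gains = plan.exposure_weights * eta

    shape_extra: tuple[int, ...] = ()
    for r in phantom.reflectors:
        a = np.asarray(r.amplitude)
        if a.ndim > 0:
            shape_extra = np.broadcast_shapes(shape_extra, a.shape)

    n = plan.n_frames
    dc = np.broadcast_to(
        reference_reflectivity + dc_background, (n, *shape_extra)
    ).copy()
    interf = np.zeros((n, *shape_extra))
    for r in phantom.reflectors:
        delta_um = phantom.opd(r)
        scale = np.array([phantom._scale(r, float(l)) for l in lam])
        a = np.asarray(r.amplitude, dtype=float)
        vis = gaussian_line_visibility(delta_um, lam, lw)
        cosine = np.cos(k * delta_um * 1000.0)
        # per-frame scalar factor, broadcast against a possible 2-D map
        term = (2.0 * np.sqrt(reference_reflectivity) * vis * cosine * scale).reshape(
            (n,) + (1,) * len(shape_extra)
        )
        interf = interf + term * a
        dc = dc + a**2

    gain_shaped = gains.reshape((n,) + (1,) * len(shape_extra))
    frames = np.maximum(gain_shaped * (dc + interf), 0.0)
    ref_frames = gain_shaped * np.broadcast_to(
        reference_reflectivity + dc_background, (n, *shape_extra)
    )

    if full_well is not None and seed is not None:
        # a relative intensity of 1.0 corresponds to the camera full well
        rng = np.random.default_rng(seed)
        if frames.max() > 1.0:
            warnings.warn("camera saturation: signal exceeds the full well", stacklevel=2)
        frames = rng.poisson(frames * full_well) / full_well
        ref_frames = rng.poisson(ref_frames * full_well) / full_well

    return KStack(plan=plan, frames=frames, reference_frames=ref_frames, gains=gains)
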