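"""Demodulation, k-space reconstruction and axial-PSF metrics.

Swept-source reconstruction follows the standard order of operations:
subtract the reference (object-arm-blocked) stack to remove incoherent
light, divide out the declared per-frame gain (exposure weight x source
efficiency), apodize along k, zero-pad, and Fourier transform in the k
dimension.  The depth axis uses the double-pass convention
depth = OPD / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from octshaper.source import TWO_PI, CalibrationTable
from octshaper.sequences import SweepPlan
from octshaper.forward import KStack, Phantom, PhaseSteppedFrames, Reflector, simulate_ss_stack

__all__ = [
    "AxialProfile",
    "PsfMetrics",
    "SIDELOBE_FLOOR_DB",
    "demodulate_2phase",
    "demodulate_4phase",
    "depth_range",
    "fwhm",
    "peak_sidelobe_db",
    "psf_metrics",
    "rolloff_curve",
    "spectral_window",
    "ss_reconstruct",
]

SIDELOBE_FLOOR_DB = -240.0

_WINDOWS = {
    "none": lambda n: np.ones(n),
    "hamming": lambda n: 0.54 - 0.46 * np.cos(TWO_PI * np.arange(n) / (n - 1)),
    "hann": lambda n: 0.5 - 0.5 * np.cos(TWO_PI * np.arange(n) / (n - 1)),
    "blackman": lambda n: 0.42
    - 0.5 * np.cos(TWO_PI * np.arange(n) / (n - 1))
    + 0.08 * np.cos(2 * TWO_PI * np.arange(n) / (n - 1)),
}


def spectral_window(name: str | None, n: int) -> NDArray[np.float64]:
    """Apodization window of length ``n`` (Hamming coefficients 0.54/0.46)."""
    key = "none" if name is None else name.lower()
    if key not in _WINDOWS:
        raise ValueError(f"unknown window {name!r}; choose from {sorted(_WINDOWS)}")
    return _WINDOWS[key](n)


@dataclass(frozen=True)
class AxialProfile:
    """Reconstructed amplitude versus depth (um) on a uniform ascending grid."""

    depth_grid: NDArray[np.float64]
    amplitude: NDArray[np.float64]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.depth_grid, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if z.ndim != 1 or z.size != a.shape[0]:
            raise ValueError("depth grid must be 1-D and match the amplitude axis 0")
        dz = np.diff(z)
        if np.any(dz <= 0) or np.max(np.abs(dz - dz[0])) > 1e-6 * dz[0] + 1e-15:
            raise ValueError("depth grid must be uniform and ascending")
        if np.any(a < 0):
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "depth_grid", z)
        object.__setattr__(self, "amplitude", a)

    @property
    def dz(self) -> float:
        return float(self.depth_grid[1] - self.depth_grid[0])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"depth_um": self.depth_grid, "amplitude": self.amplitude}
        ).to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class PsfMetrics:
    peak_depth: float  # um
    fwhm: float  # um
    peak_sidelobe_db: float  # dB, <= 0 relative to the main peak

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.peak_sidelobe_db > 0:
            raise ValueError("sidelobe level must be <= 0 dB")


def demodulate_4phase(frames: PhaseSteppedFrames) -> NDArray | float:
    """Interference amplitude from 4 frames at phases {0, pi/2, pi, 3*pi/2}.

    ``A = 0.5 * sqrt((I_0 - I_pi)**2 + (I_pi/2 - I_3pi/2)**2)`` recovers
    ``2 sqrt(R_ref R_s) |gamma|`` exactly in the noiseless model,
    independent of the interferometric phase offset.
    """
    if len(frames.phases) != 4:
        raise ValueError("demodulate_4phase needs exactly 4 phases")
    expected = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    if not np.allclose(frames.phases, expected, atol=1e-9):
        raise ValueError("phases must be {0, pi/2, pi, 3*pi/2}")
    i0, i1, i2, i3 = (np.asarray(i, dtype=float) for i in frames.intensities)
    amp = 0.5 * np.hypot(i0 - i2, i1 - i3)
    return float(amp) if amp.ndim == 0 else amp


def demodulate_2phase(frames: PhaseSteppedFrames) -> NDArray | float:
    """Interference amplitude from 2 frames at phases {0, pi}: ``|I_0 - I_pi| / 2``.

    Unlike the 4-phase variant this retains the cosine of the residual
    interferometric phase.
    """
    if len(frames.phases) != 2:
        raise ValueError("demodulate_2phase needs exactly 2 phases")
    if not np.allclose(frames.phases, (0.0, np.pi), atol=1e-9):
        raise ValueError("phases must be {0, pi}")
    i0, i1 = (np.asarray(i, dtype=float) for i in frames.intensities)
    amp = 0.5 * np.abs(i0 - i1)
    return float(amp) if amp.ndim == 0 else amp


def ss_reconstruct(
    stack: KStack,
    window: str | None = "hamming",
    zero_pad: int = 8,
    remove_dc: bool = True,
) -> AxialProfile:
    """Depth profile (or volume) from a swept-source k stack.

    Pipeline: reference subtraction -> per-frame gain flattening (the plan's
    exposure weights and the simulator-declared efficiency) -> k-mean
    removal -> apodization -> zero padding to ``zero_pad * N`` samples ->
    FFT along k.  Depth bin m sits at ``z_m = m * 2*pi / (N_pad * dk) / 2``
    (depth = OPD / 2).  In image mode the amplitude is per-pixel; a complex
    version is kept in ``meta['complex']``.

    Blocking the object arm removes the sample's own incoherent
    backscatter along with the interference term, so the reference
    subtraction leaves that single-arm intensity behind; ``remove_dc``
    subtracts the per-pixel mean along k to keep it out of the zeroth
    Fourier order.
    """
    if zero_pad < 1:
        raise ValueError("zero_pad must be >= 1")
    plan = stack.plan
    dk = plan.dk  # uniformity asserted by SweepPlan
    signal = stack.frames - stack.reference_frames
    gains = stack.gains if stack.gains is not None else plan.exposure_weights
    shape_tail = (1,) * (signal.ndim - 1)
    signal = signal / gains.reshape((-1, *shape_tail))
    n = plan.n_frames
    w = spectral_window(window, n)
    if stack.reference_frames.max() == 0:
        warnings.warn(
            "no reference stack: the DC term will dominate the reconstruction",
            stacklevel=2,
        )
    if remove_dc:
        signal = signal - signal.mean(axis=0, keepdims=True)
    signal = signal * w.reshape((-1, *shape_tail))
    n_pad = int(zero_pad) * n
    field_z = np.fft.rfft(signal, n=n_pad, axis=0)
    amplitude = np.abs(field_z)
    # OPD bin: 2*pi / (N_pad * dk) [nm]; depth = OPD / 2, reported in um
    dz_um = TWO_PI / (n_pad * dk) / 2.0 / 1000.0
    depth = np.arange(field_z.shape[0]) * dz_um
    meta = {
        "window": "none" if window is None else window,
        "zero_pad": int(zero_pad),
        "dk_rad_per_nm": dk,
        "complex": field_z,
    }
    return AxialProfile(depth_grid=depth, amplitude=amplitude, meta=meta)


def _profile_1d(profile: AxialProfile) -> NDArray[np.float64]:
    a = profile.amplitude
    return a if a.ndim == 1 else a.reshape(a.shape[0], -1).mean(axis=1)


def fwhm(profile: AxialProfile) -> float:
    """Full width at half maximum (um) of the dominant amplitude peak.

    Half-maximum crossings are located by linear interpolation on the
    amplitude (not intensity) profile.
    """
    a = _profile_1d(profile)
    z = profile.depth_grid
    ipk = int(np.argmax(a))
    if ipk in (0, a.size - 1):
        raise ValueError("peak sits at the grid edge; widen the scan range")
    half = a[ipk] / 2.0
    i = ipk
    while i > 0 and a[i] > half:
        i -= 1
    if a[i] > half:
        raise ValueError("left half-maximum crossing not inside the grid")
    zl = z[i] + (z[i + 1] - z[i]) * (half - a[i]) / (a[i + 1] - a[i])
    j = ipk
    while j < a.size - 1 and a[j] > half:
        j += 1
    if a[j] > half:
        raise ValueError("right half-maximum crossing not inside the grid")
    zr = z[j - 1] + (z[j] - z[j - 1]) * (half - a[j - 1]) / (a[j] - a[j - 1])
    return float(zr - zl)


def peak_sidelobe_db(profile: AxialProfile, exclude_dc_bins: int = 1) -> float:
    """Highest sidelobe level (dB, negative) relative to the main peak.

    The main lobe is bounded by the first local minima on each side of the
    global peak; the DC bin(s) are excluded from the search.  If no
    sidelobe rises above the numerical floor the floor value
    (:data:`SIDELOBE_FLOOR_DB`) is returned with a warning.
    """
    a = _profile_1d(profile).copy()
    if exclude_dc_bins > 0 and profile.depth_grid[0] == 0.0:
        region = slice(0, exclude_dc_bins)
        a[region] = 0.0
    ipk = int(np.argmax(a))
    peak = a[ipk]
    if peak <= 0:
        raise ValueError("profile has no peak")
    # walk to the first local minima bounding the main lobe
    left = ipk
    while left > 0 and a[left - 1] < a[left]:
        left -= 1
    right = ipk
    while right < a.size - 1 and a[right + 1] < a[right]:
        right += 1
    outside = np.concatenate([a[: max(left, 0)], a[right + 1 :]])
    floor = peak * 10 ** (SIDELOBE_FLOOR_DB / 20.0)
    if outside.size == 0 or outside.max() <= floor:
        warnings.warn("no sidelobe above the numerical floor", stacklevel=2)
        return SIDELOBE_FLOOR_DB
    return float(20.0 * np.log10(outside.max() / peak))


def psf_metrics(profile: AxialProfile) -> PsfMetrics:
    a = _profile_1d(profile)
    ipk = int(np.argmax(a))
    return PsfMetrics(
        peak_depth=float(profile.depth_grid[ipk]),
        fwhm=fwhm(profile),
        peak_sidelobe_db=min(peak_sidelobe_db(profile), 0.0),
    )


def depth_range(
    n_frames: int, lam_min: float, lam_max: float, conjugate_free: bool = True
) -> float:
    """Maximum imaging depth (um) of an ``n_frames`` k-linear sweep.

    With ``dk = (2 pi / lam_min - 2 pi / lam_max) / (n_frames - 1)``, the
    Nyquist optical path is ``pi / dk``.  Depth is OPD/2, and placing the
    sample surface at zero OPD to keep the complex-conjugate image out of
    the usable range halves it again (default); ``conjugate_free=False``
    returns the full single-sided depth.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not 0 < lam_min < lam_max:
        raise ValueError("need 0 < lam_min < lam_max")
    dk = (TWO_PI / lam_min - TWO_PI / lam_max) / (n_frames - 1)  # rad/nm
    opd_nyquist_nm = np.pi / dk
    depth_um = opd_nyquist_nm / 2.0 / 1000.0
    return float(depth_um / 2.0 if conjugate_free else depth_um)


def rolloff_curve(
    phantom_opds: Sequence[float],
    plan: SweepPlan,
    table: CalibrationTable,
    window: str | None = "hamming",
    zero_pad: int = 8,
) -> list[tuple[float, float]]:
    """Reconstructed peak amplitude (dB) versus mirror OPD (um).

    For each OPD a unit mirror is simulated at depth OPD/2, reconstructed,
    and its peak amplitude recorded in dB relative to the smallest OPD.
    The finite instantaneous linewidth makes the curve monotonically
    non-increasing (Gaussian fringe washout).
    """
    opds = np.asarray(phantom_opds, dtype=float)
    if opds.size == 0:
        raise ValueError("need at least one OPD")
    zmax = depth_range(plan.n_frames, plan.wavelengths.min(), plan.wavelengths.max(),
                       conjugate_free=False)
    if np.any(opds / 2.0 > zmax):
        raise ValueError("OPD beyond the Nyquist depth of the sweep")
    peaks = []
    for opd in opds:
        phantom = Phantom(reflectors=(Reflector(depth=opd / 2.0, amplitude=1.0),))
        stack = simulate_ss_stack(phantom, plan, table)
        prof = ss_reconstruct(stack, window=window, zero_pad=zero_pad)
        a = _profile_1d(prof)
        a[0] = 0.0  # ignore residual DC
        peaks.append(float(a.max()))
    ref = peaks[int(np.argmin(opds))]
    return [
        (float(opd), float(20.0 * np.log10(max(p, 1e-300) / ref)))
        for opd, p in zip(opds, peaks)
    ]
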