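"""Phantom generators, system geometry, file I/O and the config-driven pipeline."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from octshaper.source import CalibrationTable, FiberSpec, Spectrum, default_calibration
from octshaper.sequences import design_exposure_shaping, design_k_linear_sweep
from octshaper.forward import KStack, Phantom, Reflector, simulate_ss_stack
from octshaper.recon import depth_range, psf_metrics, ss_reconstruct
from octshaper.spectroscopy import mie_backscatter, MieParams

__all__ = [
    "RunConfig",
    "SystemGeometry",
    "load_calibration_csv",
    "load_spectrum_csv",
    "make_bead_stack",
    "make_phantom",
    "pupil_beam_diameter",
    "run_experiment",
    "sample_pixel_size",
    "save_calibration_csv",
    "save_kstack",
    "save_spectrum_csv",
    "spectroscopic_demo",
]


@dataclass(frozen=True)
class SystemGeometry:
    """Optical-train geometry of the full-field microscope.

    ``objective_reference_focal`` is the tube-length standard that turns a
    nominal magnification into a focal length (180 mm, Olympus
    convention): a "4x" objective has f = 180/4 = 45 mm, so a 300 mm tube
    lens gives a system magnification of 300/45 = 6.67.
    """

    camera_pixel: float = 12.0  # um
    tube_lens_focal: float = 300.0  # mm
    objective_magnification: float = 4.0
    objective_reference_focal: float = 180.0  # mm
    relay_magnification: float = 4.17  # fiber output -> pupil plane
    fiber: FiberSpec = field(default_factory=FiberSpec)

    def __post_init__(self) -> None:
        vals = (
            self.camera_pixel,
            self.tube_lens_focal,
            self.objective_magnification,
            self.objective_reference_focal,
            self.relay_magnification,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry parameters must be positive")

    @property
    def system_magnification(self) -> float:
        """Tube-lens focal length over objective focal length."""
        f_obj = self.objective_reference_focal / self.objective_magnification
        return self.tube_lens_focal / f_obj


def sample_pixel_size(geom: SystemGeometry) -> float:
    """Sample-plane pixel size (um): camera pixel pitch / system magnification."""
    return geom.camera_pixel / geom.system_magnification


def pupil_beam_diameter(geom: SystemGeometry) -> float:
    """Illumination beam diameter (mm) in the objective pupil plane."""
    return geom.fiber.core_diameter / 1000.0 * geom.relay_magnification


def make_phantom(kind: str, params: dict | None = None, seed: int | None = None) -> Phantom:
    """Deterministic phantom fixtures.

    kinds:
      ``mirror``      — one reflector (``depth`` um, ``amplitude``).
      ``two_mirror``  — two reflectors separated by ``opd`` um of optical
                        path (``depth`` of the first, ``amplitudes``).
      ``beads3d``     — ``n`` seeded reflectors between ``depth_min`` and
                        ``depth_max``, diameters drawn from ``diameters``
                        (nm); a fraction ``aggregate_fraction`` gets the
                        spectral response of ``aggregate_diameter``.
      ``layered``     — ``n_layers`` interfaces every ``period`` um.

    A warning is raised when two reflectors sit closer than
    ``min_separation`` um (default 0: never).
    """
    p = dict(params or {})
    min_sep = float(p.pop("min_separation", 0.0))
    medium_index = float(p.pop("medium_index", 1.0))
    rng = np.random.default_rng(seed)

    if kind == "mirror":
        reflectors = [Reflector(depth=float(p.get("depth", 6.0)),
                                amplitude=float(p.get("amplitude", 1.0)))]
        responses = {}
    elif kind == "two_mirror":
        z0 = float(p.get("depth", 5.0))
        opd = float(p.get("opd", 20.0))
        a = p.get("amplitudes", (1.0, 1.0))
        dz = opd / (2.0 * medium_index)
        reflectors = [Reflector(z0, float(a[0])), Reflector(z0 + dz, float(a[1]))]
        responses = {}
    elif kind == "beads3d":
        n = int(p.get("n", 50))
        zlo, zhi = float(p.get("depth_min", 2.0)), float(p.get("depth_max", 40.0))
        diameters = list(p.get("diameters", (990.0, 505.0)))
        agg_frac = float(p.get("aggregate_fraction", 0.0))
        agg_d = float(p.get("aggregate_diameter", 5000.0))
        depths = rng.uniform(zlo, zhi, n)
        chosen = rng.choice(diameters, n)
        is_agg = rng.random(n) < agg_frac
        reflectors = []
        responses = {}
        for i in range(n):
            d_eff = agg_d if is_agg[i] else float(chosen[i])
            rid = f"d{d_eff:.0f}"
            responses.setdefault(rid, _mie_amplitude_response(d_eff))
            reflectors.append(
                Reflector(depth=float(depths[i]), amplitude=0.1, spectral_response_id=rid)
            )
    elif kind == "layered":
        n_layers = int(p.get("n_layers", 5))
        period = float(p.get("period", 8.0))
        z0 = float(p.get("depth", 4.0))
        amp = float(p.get("amplitude", 0.3))
        reflectors = [Reflector(z0 + i * period, amp) for i in range(n_layers)]
        responses = {}
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    depths = np.sort([r.depth for r in reflectors])
    if min_sep > 0 and depths.size > 1 and np.any(np.diff(depths) < min_sep):
        warnings.warn(
            "reflectors closer than the axial resolution will not be resolved",
            stacklevel=2,
        )
    return Phantom(reflectors=tuple(reflectors), medium_index=medium_index,
                   spectral_responses=responses)


def _mie_amplitude_response(diameter_nm: float):
    """Amplitude spectral response (sqrt of Q_back, peak-normalized) of a sphere."""
    lam = np.linspace(650.0, 1000.0, 36)
    spec = mie_backscatter(
        MieParams(diameter=diameter_nm, particle_index=1.59, medium_index=1.34,
                  wavelengths=lam)
    )
    amp = np.sqrt(spec.density)
    amp = amp / amp.max()

    def response(lam_nm: float) -> float:
        return float(np.interp(lam_nm, spec.grid, amp))

    return response


def make_bead_stack(
    wavelengths,
    n_particles: int = 200,
    class_diameters: tuple[float, float] = (990.0, 505.0),
    aggregate_fraction: float = 0.3,
    aggregate_diameter: float = 5000.0,
    particle_index: float = 1.59,
    medium_index: float = 1.34,
    image_shape: tuple[int, int] = (420, 420),
    blob_sigma: float = 2.0,
    noise_sigma: float = 0.05,
    seed: int | None = None,
):
    """Synthetic wavelength-series amplitude stack of a bead phantom.

    Each particle is a Gaussian blob whose per-wavelength peak amplitude
    follows the Mie backscattering efficiency of its class (990 or 505 nm
    diameter spheres), with ``aggregate_fraction`` of the particles
    replaced by aggregates carrying the response of a larger effective
    sphere.  Particles sit on a jittered grid (no accidental merging),
    brightness is log-normal, and additive Gaussian noise (clipped at
    zero) models the detection floor.

    Returns ``(stack, labels, positions, templates)`` with ``stack`` of
    shape ``(n_wavelengths, H, W)``, integer ``labels`` (0/1 = bead class,
    2 = aggregate), the true (row, col) ``positions`` for matching against
    segmented centroids, and the peak-normalized template spectra, one row
    per label.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(wavelengths, dtype=float)
    diameters = (*class_diameters, aggregate_diameter)
    templates = np.empty((3, lam.size))
    for i, d in enumerate(diameters):
        q = mie_backscatter(
            MieParams(diameter=d, particle_index=particle_index,
                      medium_index=medium_index, wavelengths=lam)
        )
        dens = np.interp(lam, q.grid, q.density)
        templates[i] = dens / dens.max()

    h, w = image_shape
    n_cells = int(np.ceil(np.sqrt(n_particles)))
    cell_h, cell_w = h / n_cells, w / n_cells
    cells = rng.permutation(n_cells * n_cells)[:n_particles]
    labels = np.empty(n_particles, dtype=int)
    positions = np.empty((n_particles, 2))
    stack = np.zeros((lam.size, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for i, cell in enumerate(cells):
        r0 = (cell // n_cells + 0.5) * cell_h + rng.uniform(-0.15, 0.15) * cell_h
        c0 = (cell % n_cells + 0.5) * cell_w + rng.uniform(-0.15, 0.15) * cell_w
        positions[i] = r0, c0
        labels[i] = 2 if rng.random() < aggregate_fraction else int(rng.integers(0, 2))
        brightness = float(rng.lognormal(mean=0.0, sigma=0.25))
        blob = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * blob_sigma**2)))
        stack += brightness * templates[labels[i]][:, None, None] * blob[None, :, :]
    stack += rng.normal(0.0, noise_sigma, stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return stack, labels, positions, templates


def spectroscopic_demo(
    seed: int = 0,
    n_particles: int = 200,
    aggregate_fraction: float = 0.3,
    wavelengths=None,
    n_components: int = 3,
) -> dict:
    """Full synthetic spectroscopy pipeline: beads -> segment -> extract -> PCA.

    Generates a wavelength-series bead stack, segments particles on the
    wavelength-summed image, extracts per-particle spectra, PCA-filters
    them, assigns each particle to the nearest normalized template
    (990 nm bead / 505 nm bead / aggregate), and scores the assignment
    against the generated ground truth (particles matched by centroid).
    """
    from octshaper.spectroscopy import (
        extract_particle_spectra,
        pca_filter_spectra,
        segment_particles,
    )

    if wavelengths is None:
        wavelengths = np.arange(750.0, 951.0, 25.0)
    lam = np.asarray(wavelengths, dtype=float)
    stack, labels, positions, templates = make_bead_stack(
        lam, n_particles=n_particles, aggregate_fraction=aggregate_fraction, seed=seed
    )
    masks = segment_particles(stack.sum(axis=0), threshold_sigma=3.0, min_area=4)
    spectra = extract_particle_spectra(stack, masks, lam)
    filtered, energy = pca_filter_spectra(spectra, n_components=n_components)

    norm_templates = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    rows = filtered.matrix
    rows = rows / np.clip(np.linalg.norm(rows, axis=1, keepdims=True), 1e-12, None)
    assigned = np.argmin(
        np.linalg.norm(rows[:, None, :] - norm_templates[None, :, :], axis=2), axis=1
    )
    # match each segmented particle to the nearest generated one
    d2 = (
        (filtered.particle_centroids[:, None, :] - positions[None, :, :]) ** 2
    ).sum(axis=2)
    truth = labels[np.argmin(d2, axis=1)]
    accuracy = float(np.mean(assigned == truth)) if assigned.size else 0.0
    return {
        "n_segmented": int(len(masks)),
        "accuracy": accuracy,
        "explained_energy": energy.tolist(),
        "assigned": assigned,
        "truth": truth,
        "filtered": filtered,
        "templates": templates,
        "wavelengths": lam,
    }


# ---------------------------------------------------------------------------
# file I/O


def save_calibration_csv(table: CalibrationTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "voltage_V": table.voltage_nodes,
            "wavelength_nm": table.wavelength_nodes,
            "linewidth_nm": table.linewidth_nodes,
            "efficiency": table.efficiency_nodes,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def load_calibration_csv(path: str | Path) -> CalibrationTable:
    df = pd.read_csv(path)
    return CalibrationTable(
        df["voltage_V"].to_numpy(),
        df["wavelength_nm"].to_numpy(),
        df["linewidth_nm"].to_numpy(),
        df["efficiency"].to_numpy(),
    )


def save_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    lam = spectrum.to_wavelength()
    pd.DataFrame({"wavelength_nm": lam.grid, "density": lam.density}).to_csv(
        path, index=False, float_format="%.9g"
    )


def load_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["density"].to_numpy(), "wavelength")


def save_kstack(stack: KStack, path: str | Path) -> None:
    """Multi-page TIFF (frames in ascending-k order) plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    frames = stack.frames
    if frames.ndim == 1:
        frames = frames[:, None, None]
    tifffile.imwrite(path, frames.astype(np.float32))
    ref = stack.reference_frames
    if ref.ndim == 1:
        ref = ref[:, None, None]
    tifffile.imwrite(path.with_name(path.stem + "_reference.tif"), ref.astype(np.float32))
    sidecar = {
        "wavelength_nm": stack.plan.wavelengths.tolist(),
        "wavenumber_rad_per_nm": stack.plan.wavenumbers.tolist(),
        "exposure_weight": stack.plan.exposure_weights.tolist(),
        "gains": None if stack.gains is None else stack.gains.tolist(),
        "frame_order": "k ascending",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# config-driven pipeline


@dataclass(frozen=True)
class RunConfig:
    """One swept-source experiment: sweep design, phantom, reconstruction."""

    band: tuple[float, float] = (650.0, 950.0)
    n_frames: int = 250
    window: str = "hamming"
    zero_pad: int = 8
    seed: int = 0
    shape_exposure: bool = True
    phantom_kind: str = "mirror"
    phantom_params: dict = field(default_factory=lambda: {"depth": 6.0})
    outdir: str = "octshaper_run"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig, table: CalibrationTable | None = None) -> dict:
    """Design -> simulate -> reconstruct -> metrics, with provenance on disk.

    Writes the k stack (TIFF + JSON sidecar), the axial profile (CSV) and a
    metrics JSON carrying the seed, config hash and package version.
    Reruns of the same config are byte-identical for CSV/JSON outputs.
    Stage failures are re-raised with a stage-tagged message and no partial
    outputs are kept.
    """
    table = table or default_calibration()
    outdir = Path(config.outdir)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    plan = _stage(
        "design", design_k_linear_sweep, config.band[0], config.band[1],
        config.n_frames, table,
    )
    if config.shape_exposure:
        plan = _stage("design", design_exposure_shaping, plan, table)
    phantom = _stage("phantom", make_phantom, config.phantom_kind,
                     config.phantom_params, config.seed)
    stack = _stage("simulate", simulate_ss_stack, phantom, plan, table)
    profile = _stage("reconstruct", ss_reconstruct, stack,
                     window=config.window, zero_pad=config.zero_pad)
    metrics = _stage("metrics", psf_metrics, profile)

    outdir.mkdir(parents=True, exist_ok=True)
    save_kstack(stack, outdir / "kstack.tif")
    profile.to_csv(outdir / "axial_profile.csv")
    from octshaper import __version__

    payload = {
        "fwhm_um": metrics.fwhm,
        "peak_depth_um": metrics.peak_depth,
        "peak_sidelobe_db": metrics.peak_sidelobe_db,
        "depth_range_um": depth_range(config.n_frames, *config.band),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
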