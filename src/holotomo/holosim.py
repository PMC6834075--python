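"""Forward simulation of partial-coherence in-line holograms.

The chain is: projected thickness maps -> complex transmission (projection
approximation) -> free-space Fresnel propagation (transfer-function method)
-> partial-coherence blur (detector-plane convolution with the demagnified
effective source) -> photon counting (Poisson).  Illumination is a
monochromatic plane wave; beam divergence from the finite source distance is
folded in, when relevant, through the effective propagation distance
z_eff = z L / (L + z) and transverse magnification M = (L + z) / L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import optics
from .phantom import ThicknessMaps, VoxelPhantom, project_thickness

__all__ = [
    "ComplexField", "Hologram", "ProjectionStack", "AliasingError",
    "transmit", "propagate", "apply_partial_coherence", "record",
    "cone_to_parallel", "simulate_tomo_series",
]


class AliasingError(ValueError):
    """Propagation distance too large for the sampled field."""


@dataclass
class ComplexField:
    """Sampled complex amplitude (1D profile or 2D image)."""

    data: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite values")

    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2


@dataclass
class Hologram:
    """Detector-plane intensity image with its acquisition metadata."""

    data: np.ndarray
    pitch: float
    z: float
    energy_kev: float
    flux_density: float | None = None   # photons s^-1 mm^-2
    exposure: float | None = None       # s
    seed: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("hologram intensities must be non-negative")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be positive")


@dataclass
class ProjectionStack:
    """Ordered tomographic projection series with uniform angular steps."""

    frames: np.ndarray              # (n_angles, ny, nx)
    angles_deg: np.ndarray          # relative angles, uniform spacing
    pitch: float
    z: float
    energy_kev: float
    offset_unknown: bool = False    # absolute angles were not registered
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        if len(self.angles_deg) != len(self.frames):
            raise ValueError("one angle per frame required")
        if len(self.angles_deg) > 1:
            steps = np.diff(self.angles_deg)
            if not np.allclose(steps, steps[0], atol=1e-9):
                raise ValueError("angular spacing must be uniform")


def transmit(maps: ThicknessMaps, energy_kev: float) -> ComplexField:
    """Complex transmission of thickness maps in the projection approximation.

    amplitude = exp(-sum mu_m t_m / 2), phase = -(2 pi / lambda) sum delta_m t_m.
    """
    lam = optics.wavelength_from_energy(energy_kev)
    mu_t = np.zeros(maps.shape)
    phase = np.zeros(maps.shape)
    for material, t in maps.maps.items():
        oc = optics.optical_constants(material, energy_kev)
        mu_t += oc.mu * t
        phase -= 2.0 * np.pi / lam * oc.delta * t
    data = np.exp(-0.5 * mu_t) * np.exp(1j * phase)
    return ComplexField(data, maps.pixel, lam)


def propagate(fld: ComplexField, z: float) -> ComplexField:
    """Fresnel free-space propagation by the transfer-function method.

    The angular-spectrum Fresnel kernel H(f) = exp(-i pi lambda z |f|^2)
    (f in cycles per length) is applied in frequency space; |H| = 1, so the
    total intensity is conserved.  The field must be sampled finely enough
    that the Fresnel spreading lambda*z/pitch fits inside the field extent.
    """
    if z == 0:
        return ComplexField(fld.data.copy(), fld.pitch, fld.wavelength)
    data = fld.data
    shape = [n for n in data.shape if n > 1]
    if shape:
        extent = min(shape) * fld.pitch
        spread = fld.wavelength * abs(z) / fld.pitch
        if spread > extent:
            raise AliasingError(
                f"lambda*z/pitch = {spread:.3e} m exceeds the field extent "
                f"{extent:.3e} m (z = {z} m, pitch = {fld.pitch} m); "
                "enlarge the field or reduce z"
            )
    freqs = [np.fft.fftfreq(n, d=fld.pitch) for n in data.shape]
    f2 = np.zeros(data.shape)
    for ax, f in enumerate(freqs):
        sh = [1] * data.ndim
        sh[ax] = len(f)
        f2 = f2 + (f.reshape(sh)) ** 2
    kernel = np.exp(-1j * np.pi * fld.wavelength * z * f2)
    out = np.fft.ifftn(np.fft.fftn(data) * kernel)
    return ComplexField(out, fld.pitch, fld.wavelength)


def apply_partial_coherence(intensity: np.ndarray, source: optics.SourceModel,
                            z: float, pitch: float) -> np.ndarray:
    """Blur an intensity pattern by the projected effective source.

    In shadow geometry a source of FWHM d at distance L smears detector
    features over d * z / L, so the coherent intensity is convolved with an
    anisotropic Gaussian of that FWHM (vertical = rows, horizontal =
    columns).  Circular convolution keeps the mean intensity exact.
    """
    if z < 0:
        raise ValueError("propagation distance must be non-negative")
    if z == 0:
        return np.asarray(intensity, dtype=float).copy()
    d_v, d_h = source.effective_fwhm()
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sig_v = d_v * z / source.distance * fwhm_to_sigma / pitch
    sig_h = d_h * z / source.distance * fwhm_to_sigma / pitch
    arr = np.asarray(intensity, dtype=float)
    if arr.ndim == 1:
        return ndimage.gaussian_filter1d(arr, sig_v, mode="wrap") if sig_v > 0 else arr.copy()
    sigma = (sig_v, sig_h)
    if max(sigma) == 0:
        return arr.copy()
    return ndimage.gaussian_filter(arr, sigma, mode="wrap")


def record(intensity: np.ndarray, flat: np.ndarray | None,
           flux_density: float, exposure: float, energy_kev: float,
           pitch: float, z: float = 0.0,
           seed: int | None = None) -> Hologram:
    """Convert relative intensity to detector counts.

    Expected counts per pixel are intensity * flat * flux_density (photons
    s^-1 mm^-2) * pixel area * exposure.  With a seed the counts are Poisson
    draws; without, the expectation itself is returned.
    """
    if flux_density < 0 or exposure < 0:
        raise ValueError("flux density and exposure must be non-negative")
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensity must be non-negative")
    expected = arr * flux_density * (pitch * 1e3) ** 2 * exposure
    if flat is not None:
        expected = expected * np.asarray(flat, dtype=float)
    if seed is not None:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return Hologram(counts, pitch, z, energy_kev, flux_density, exposure, seed)


def cone_to_parallel(z: float, source_distance: float) -> tuple[float, float]:
    """Effective parallel-beam distance and magnification for a point source.

    Divergent illumination from a source at distance L is equivalent to
    plane-wave propagation over z_eff = z L / (L + z) followed by transverse
    magnification M = (L + z) / L.
    """
    if z < 0 or source_distance <= 0:
        raise ValueError("z must be >= 0 and source distance > 0")
    return z * source_distance / (source_distance + z), (source_distance + z) / source_distance


def simulate_tomo_series(phantom: VoxelPhantom, z: float, energy_kev: float,
                         n_angles: int = 180, step_deg: float = 1.0,
                         flux_density: float = 1e13, exposure: float = 0.017,
                         source: optics.SourceModel | None = None,
                         flats: list[np.ndarray] | None = None,
                         angle_offset_deg: float = 0.0,
                         seed: int | None = None) -> tuple[ProjectionStack, list[np.ndarray]]:
    """Simulate a full tomographic projection series plus matching flats.

    For each angle the chain project -> transmit -> propagate -> source blur
    -> record is run; an illumination pattern from ``flats`` (relative gain
    maps, e.g. from :func:`holotomo.phantom.make_flat_fields`) is picked at
    random per exposure, emulating beam fluctuations.  Each gain map is also
    recorded once without a sample, and those count images are returned as
    the flat-field pool for downstream correction.  ``angle_offset_deg``
    rotates the whole series rigidly, emulating an unregistered absolute
    angle origin.  The per-frame flat indices end up in ``stack.meta``.
    """
    rng = np.random.default_rng(seed)
    angles = angle_offset_deg + step_deg * np.arange(n_angles)
    frames = []
    used_flats: list[int] = []
    for ang in angles:
        maps = project_thickness(phantom, ang)
        fld = transmit(maps, energy_kev)
        fld = propagate(fld, z)
        inten = fld.intensity()
        if source is not None:
            inten = apply_partial_coherence(inten, source, z, phantom.voxel_size)
        flat = None
        idx = -1
        if flats:
            idx = int(rng.integers(len(flats)))
            flat = flats[idx]
        frame_seed = int(rng.integers(2**31)) if seed is not None else None
        holo = record(inten, flat, flux_density, exposure, energy_kev,
                      phantom.voxel_size, z, frame_seed)
        frames.append(holo.data)
        used_flats.append(idx)
    ny, nx = frames[0].shape
    recorded_flats: list[np.ndarray] = []
    for gain in (flats or []):
        flat_seed = int(rng.integers(2**31)) if seed is not None else None
        holo = record(np.ones((ny, nx)), gain, flux_density, exposure,
                      energy_kev, phantom.voxel_size, z, flat_seed)
        recorded_flats.append(holo.data)
    stack = ProjectionStack(
        np.stack(frames), step_deg * np.arange(n_angles), phantom.voxel_size,
        z, energy_kev, offset_unknown=angle_offset_deg != 0.0,
        meta={"flux_density": flux_density, "exposure": exposure, "seed": seed,
              "flat_indices": used_flats},
    )
    return stack, recorded_flats
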