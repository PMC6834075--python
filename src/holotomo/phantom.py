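"""Synthetic sample generators.

Two imaging situations are emulated: a boron fiber with a tungsten core used
to characterize beam coherence, and protein crystals embedded in a slab of
lipidic cubic phase (LCP) on a kapton mount, the sample type the tomography
pipeline targets.  Phantoms carry per-material projected thickness maps
(the input of the wave-optical forward model) or labelled voxel volumes with
ground truth for validating the reconstruction/segmentation chain.

Conventions: rotation axis vertical (array axis 0), angles counter-clockwise
viewed from above, image row 0 at top, pixel centers at half-integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import materials

__all__ = [
    "MaterialSpec", "VoxelPhantom", "ThicknessMaps", "GroundTruth",
    "make_fiber_phantom", "make_crystal_mount_phantom", "project_thickness",
    "make_flat_fields",
]


@dataclass(frozen=True)
class MaterialSpec:
    material: str
    role: str           # fiber-shell, fiber-core, crystal, matrix, mount, background
    density: float | None = None

    def __post_init__(self):
        materials.canonical_name(self.material)
        dens = self.density if self.density is not None else 0.0
        if self.density is not None and dens <= 0:
            raise ValueError("density must be positive")


@dataclass
class ThicknessMaps:
    """Per-material projected thickness images (metres)."""

    maps: dict[str, np.ndarray]
    pixel: float
    angle_deg: float = 0.0

    def __post_init__(self):
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("all thickness maps must share one shape")
        if self.pixel <= 0:
            raise ValueError("pixel pitch must be positive")
        for name, t in self.maps.items():
            if np.any(t < -1e-12):
                raise ValueError(f"negative thickness in map {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape


@dataclass
class GroundTruth:
    n_crystals: int
    centroids: np.ndarray      # (n, 3) voxel coordinates (z, y, x)
    volumes: np.ndarray        # (n,) voxel counts


@dataclass
class VoxelPhantom:
    labels: np.ndarray                      # 3D integer grid
    voxel_size: float                       # m
    material_map: dict[int, MaterialSpec]   # label -> material
    ground_truth: GroundTruth = field(default=None)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        present = set(np.unique(self.labels))
        missing = present - set(self.material_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no material mapping")


# label conventions for the crystal-mount phantom
LABEL_BACKGROUND = 0
LABEL_MATRIX = 1
LABEL_MOUNT = 2
LABEL_CRYSTAL = 3   # all crystals share one material label


def make_fiber_phantom(diameter: float = 100e-6, core_diameter: float = 15e-6,
                       pixel: float = 0.6e-6,
                       field_px: tuple[int, int] = (2048, 64)) -> ThicknessMaps:
    """Analytic chord thicknesses of a boron fiber with a tungsten core.

    The fiber axis is horizontal (along image columns), so thickness varies
    with the row coordinate only.  The shell thickness is the full-cylinder
    chord minus the core chord.
    """
    if not 0 < core_diameter < diameter:
        raise ValueError("need 0 < core_diameter < diameter")
    ny, nx = field_px
    if ny * pixel < diameter + 400e-6:
        raise ValueError(
            f"field height {ny * pixel * 1e6:.0f} um too small for a "
            f"{diameter * 1e6:.0f} um fiber plus 200 um margins"
        )
    y = (np.arange(ny) + 0.5 - ny / 2) * pixel
    r_shell = diameter / 2.0
    r_core = core_diameter / 2.0
    chord_full = 2.0 * np.sqrt(np.clip(r_shell**2 - y**2, 0.0, None))
    t_core = 2.0 * np.sqrt(np.clip(r_core**2 - y**2, 0.0, None))
    t_shell = chord_full - t_core
    return ThicknessMaps(
        maps={
            "boron": np.repeat(t_shell[:, None], nx, axis=1),
            "tungsten": np.repeat(t_core[:, None], nx, axis=1),
        },
        pixel=pixel,
    )


def _random_convex_crystal(rng: np.random.Generator, radius_vox: float,
                           n_planes: int = 14) -> np.ndarray:
    """Boolean mask of a random convex polyhedron inside its bounding box."""
    normals = rng.normal(size=(n_planes, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    offsets = rng.uniform(0.7, 1.0, size=n_planes) * radius_vox
    half = int(np.ceil(radius_vox)) + 1
    ax = np.arange(-half, half + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)          # (D,D,D,3)
    inside = np.ones(pts.shape[:3], dtype=bool)
    for n_vec, off in zip(normals, offsets):
        inside &= pts @ n_vec <= off
    # voxelization of a thin convex body can split into face-disconnected
    # pieces; keep only the largest component so one crystal stays one object
    comp, n_comp = ndimage.label(inside)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   np.arange(1, n_comp + 1))
        inside = comp == (1 + int(np.argmax(sizes)))
    return inside


def make_crystal_mount_phantom(n_crystals: int = 20,
                               size_range: tuple[float, float] = (10e-6, 50e-6),
                               slab_thickness: float = 100e-6,
                               voxel: float = 2e-6,
                               grid: int = 256,
                               min_gap: float = 10e-6,
                               seed: int = 0,
                               max_tries: int = 2000) -> VoxelPhantom:
    """Random convex crystals inside an LCP slab held by a kapton mount.

    The slab is a plate of LCP (modelled as lipid) normal to the x axis; a
    thin kapton frame surrounds it, emulating a micromesh mount.  Crystals
    are non-overlapping convex polyhedra with diameters drawn uniformly from
    ``size_range`` and at least ``min_gap`` surface separation.  Everything
    is kept inside a centred cylinder of radius 0.45*grid voxels so that
    projections at any angle stay inside the field of view.
    """
    if n_crystals < 0:
        raise ValueError("n_crystals must be non-negative")
    if size_range[0] < 3 * voxel:
        raise ValueError("smallest crystal must span at least 3 voxels")
    rng = np.random.default_rng(seed)
    n = grid
    labels = np.zeros((n, n, n), dtype=np.uint8)

    center = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    r_cyl = np.hypot(yy - center, xx - center)
    safe_r = 0.45 * n

    # LCP slab normal to x, spanning the safe region vertically and in y
    half_slab = 0.5 * slab_thickness / voxel
    slab = (np.abs(xx - center) <= half_slab) & (r_cyl <= safe_r) \
        & (np.abs(zz - center) <= safe_r)
    labels[slab] = LABEL_MATRIX

    # kapton frame: a short collar around the slab rim
    frame_w = max(1, int(round(4e-6 / voxel)))
    frame = (np.abs(xx - center) <= half_slab + frame_w) \
        & (r_cyl <= safe_r) & (r_cyl >= safe_r - 3 * frame_w) \
        & (np.abs(zz - center) <= safe_r)
    labels[frame & (labels == 0)] = LABEL_MOUNT

    centers: list[np.ndarray] = []
    radii: list[float] = []
    placed = 0
    tries = 0
    gap_vox = min_gap / voxel
    while placed < n_crystals:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_crystals} crystals after {max_tries} "
                "tries; loosen the packing parameters"
            )
        radius_vox = 0.5 * rng.uniform(*size_range) / voxel
        # keep crystals inside the slab interior and the safe cylinder
        cz = rng.uniform(center - safe_r + radius_vox + 2,
                         center + safe_r - radius_vox - 2)
        cy = rng.uniform(center - safe_r + radius_vox + 2,
                         center + safe_r - radius_vox - 2)
        cx = rng.uniform(center - half_slab + radius_vox,
                         center + half_slab - radius_vox) \
            if half_slab > radius_vox else center
        cand = np.array([cz, cy, cx])
        if np.hypot(cy - center, cx - center) > safe_r - radius_vox - 3 * frame_w - gap_vox:
            continue
        ok = all(np.linalg.norm(cand - c) >= radius_vox + r + gap_vox
                 for c, r in zip(centers, radii))
        if not ok:
            continue
        mask = _random_convex_crystal(rng, radius_vox)
        if mask.sum() < 3:
            continue
        half = mask.shape[0] // 2
        z0, y0, x0 = (int(round(c)) - half for c in cand)
        sl = tuple(slice(o, o + mask.shape[i]) for i, o in enumerate((z0, y0, x0)))
        if any(s.start < 0 or s.stop > n for s in sl):
            continue
        labels[sl][mask] = LABEL_CRYSTAL
        centers.append(cand)
        radii.append(radius_vox)
        placed += 1

    gt = _ground_truth_from_labels(labels)
    material_map = {
        LABEL_BACKGROUND: MaterialSpec("water", "background"),
        LABEL_MATRIX: MaterialSpec("lipid", "matrix"),
        LABEL_MOUNT: MaterialSpec("kapton", "mount"),
        LABEL_CRYSTAL: MaterialSpec("protein", "crystal"),
    }
    return VoxelPhantom(labels, voxel, material_map, gt)


def _ground_truth_from_labels(labels: np.ndarray) -> GroundTruth:
    comp, n_comp = ndimage.label(labels == LABEL_CRYSTAL)
    if n_comp == 0:
        return GroundTruth(0, np.zeros((0, 3)), np.zeros(0, dtype=int))
    idx = np.arange(1, n_comp + 1)
    centroids = np.array(ndimage.center_of_mass(labels == LABEL_CRYSTAL, comp, idx))
    volumes = ndimage.sum_labels(np.ones_like(comp), comp, idx).astype(int)
    return GroundTruth(n_comp, centroids, volumes)


def project_thickness(phantom: VoxelPhantom, angle_deg: float) -> ThicknessMaps:
    """Parallel-beam per-material thickness maps at one rotation angle.

    The volume is rotated about the vertical axis (counter-clockwise viewed
    from above) and integrated along the beam (axis 1 after rotation), so a
    map pixel holds the path length through each material in metres.
    Vacuum/background contributes nothing.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    maps: dict[str, np.ndarray] = {}
    for label, spec in phantom.material_map.items():
        if spec.role == "background":
            continue
        occ = (phantom.labels == label).astype(np.float32)
        if angle_deg % 360.0 != 0.0:
            occ = ndimage.rotate(occ, angle_deg, axes=(2, 1), reshape=False,
                                 order=1, prefilter=False)
        t = occ.sum(axis=1) * phantom.voxel_size
        key = materials.canonical_name(spec.material)
        maps[key] = maps.get(key, 0.0) + np.clip(t, 0.0, None)
    return ThicknessMaps(maps=maps, pixel=phantom.voxel_size, angle_deg=angle_deg)


def make_flat_fields(n: int = 30, field_px: tuple[int, int] = (256, 256),
                     structure_amplitude: float = 0.02,
                     gain_dispersion: float = 0.08,
                     seed: int = 0) -> list[np.ndarray]:
    """Synthetic sample-free illumination images.

    Each flat is a fixed per-pixel detector gain (shared by all flats,
    relative dispersion ``gain_dispersion``) times a smooth low-frequency
    illumination profile that varies from flat to flat with relative
    amplitude ``structure_amplitude``, emulating beam fluctuations between
    exposures.  All values are strictly positive; mean is ~1.
    """
    if n < 1:
        raise ValueError("need at least one flat field")
    rng = np.random.default_rng(seed)
    ny, nx = field_px
    gain = 1.0 + gain_dispersion * rng.standard_normal((ny, nx))
    gain = np.clip(gain, 0.05, None)
    sigma = max(ny, nx) / 10.0
    flats = []
    for _ in range(n):
        noise = rng.standard_normal((ny, nx))
        smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
        std = smooth.std()
        if std > 0:
            smooth /= std
        flat = gain * (1.0 + structure_amplitude * smooth)
        flats.append(np.clip(flat, 0.05, None))
    return flats
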