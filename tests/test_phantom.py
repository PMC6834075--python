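"""Unit tests for the synthetic sample generators."""

import numpy as np
import pytest
from scipy import ndimage

from holotomo import phantom as ph


def test_fiber_chords_analytic():
    maps = ph.make_fiber_phantom(diameter=100e-6, core_diameter=15e-6,
                                 pixel=0.5e-6, field_px=(1200, 4))
    boron = maps.maps["boron"][:, 0]
    tungsten = maps.maps["tungsten"][:, 0]
    n = len(boron)
    y = (np.arange(n) + 0.5 - n / 2) * 0.5e-6
    # on-axis: shell chord = D - d_core, core chord = d_core
    i0 = np.argmin(np.abs(y))
    assert tungsten[i0] == pytest.approx(15e-6, rel=0.01)
    assert boron[i0] + tungsten[i0] == pytest.approx(100e-6, rel=0.01)
    # outside the fiber: zero
    assert boron[0] == 0.0 and tungsten[0] == 0.0
    # total chord never exceeds the diameter
    assert np.all(boron + tungsten <= 100e-6 + 1e-12)


def test_fiber_phantom_validation():
    with pytest.raises(ValueError):
        ph.make_fiber_phantom(core_diameter=200e-6)
    with pytest.raises(ValueError):
        ph.make_fiber_phantom(field_px=(100, 4))  # too small a field


def test_mount_phantom_ground_truth_count_and_connectivity():
    phant = ph.make_crystal_mount_phantom(
        n_crystals=8, size_range=(24e-6, 50e-6), slab_thickness=120e-6,
        voxel=4e-6, grid=128, min_gap=25e-6, seed=3)
    gt = phant.ground_truth
    assert gt.n_crystals == 8
    # every crystal is one face-connected component
    comp, n_comp = ndimage.label(phant.labels == ph.LABEL_CRYSTAL)
    assert n_comp == 8
    assert len(gt.centroids) == 8 and len(gt.volumes) == 8
    assert np.all(gt.volumes >= 3)


def test_mount_phantom_deterministic():
    kwargs = dict(n_crystals=4, size_range=(24e-6, 40e-6), voxel=4e-6,
                  grid=96, min_gap=25e-6, seed=11)
    a = ph.make_crystal_mount_phantom(**kwargs)
    b = ph.make_crystal_mount_phantom(**kwargs)
    assert np.array_equal(a.labels, b.labels)


def test_mount_phantom_geometry():
    phant = ph.make_crystal_mount_phantom(
        n_crystals=5, size_range=(24e-6, 40e-6), voxel=4e-6, grid=96,
        min_gap=25e-6, seed=2)
    n = 96
    center = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
    r = np.hypot(yy - center, xx - center)
    # everything stays inside the safe cylinder
    occupied = phant.labels > 0
    assert np.all(r[occupied] <= 0.45 * n + 1.0)
    # crystals live inside the matrix slab
    crystal = phant.labels == ph.LABEL_CRYSTAL
    half_slab = 0.5 * 120e-6 / 4e-6
    assert np.all(np.abs(xx[crystal] - center) <= half_slab + 1.0)


def test_mount_phantom_packing_failure():
    with pytest.raises(RuntimeError):
        ph.make_crystal_mount_phantom(
            n_crystals=500, size_range=(30e-6, 50e-6), voxel=4e-6,
            grid=64, min_gap=25e-6, seed=0, max_tries=50)


def test_project_thickness_zero_angle_sums_columns():
    phant = ph.make_crystal_mount_phantom(
        n_crystals=2, size_range=(24e-6, 40e-6), voxel=4e-6, grid=64,
        min_gap=25e-6, seed=5)
    maps = ph.project_thickness(phant, 0.0)
    occ = (phant.labels == ph.LABEL_CRYSTAL).sum(axis=1) * 4e-6
    assert np.allclose(maps.maps["protein"], occ, atol=1e-12)
    # total projected volume is conserved under rotation (away from edges)
    maps45 = ph.project_thickness(phant, 45.0)
    v0 = maps.maps["protein"].sum()
    v45 = maps45.maps["protein"].sum()
    assert v45 == pytest.approx(v0, rel=0.05)


def test_thickness_maps_validation():
    with pytest.raises(ValueError):
        ph.ThicknessMaps({"water": np.zeros((4, 4)),
                          "protein": np.zeros((5, 5))}, pixel=1e-6)
    with pytest.raises(ValueError):
        ph.ThicknessMaps({"water": -np.ones((4, 4))}, pixel=1e-6)


def test_flat_fields_statistics():
    flats = ph.make_flat_fields(n=6, field_px=(64, 64), seed=4)
    assert len(flats) == 6
    for flat in flats:
        assert np.all(flat > 0)
        assert flat.mean() == pytest.approx(1.0, abs=0.05)
    # flats share the pixel gain but differ in low-frequency structure
    assert not np.array_equal(flats[0], flats[1])
    ratio = flats[0] / flats[1]
    assert ratio.std() < 0.05  # smooth illumination difference only


def test_material_spec_validation():
    with pytest.raises(ValueError):
        ph.MaterialSpec("water", "matrix", density=-1.0)
    with pytest.raises(Exception):
        ph.MaterialSpec("kryptonite", "matrix")
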