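"""Unit tests for the hologram forward model."""

import numpy as np
import pytest

from holotomo import holosim, optics
from holotomo.phantom import ThicknessMaps, make_crystal_mount_phantom, \
    make_flat_fields


def _simple_maps(n=128, pitch=1e-6):
    y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r2 = ((y - n / 2) ** 2 + (x - n / 2) ** 2) / (n / 8) ** 2
    return ThicknessMaps({"protein": 20e-6 * np.exp(-r2)}, pixel=pitch)


def test_transmit_amplitude_and_phase():
    maps = _simple_maps()
    fld = holosim.transmit(maps, 12.7)
    oc = optics.optical_constants("protein", 12.7)
    t = maps.maps["protein"]
    assert np.allclose(np.abs(fld.data), np.exp(-0.5 * oc.mu * t))
    lam = optics.wavelength_from_energy(12.7)
    expected_phase = -2 * np.pi / lam * oc.delta * t
    # phases agree modulo 2 pi
    assert np.allclose(np.angle(fld.data * np.exp(-1j * expected_phase)),
                       0.0, atol=1e-9)


def test_propagate_conserves_energy():
    fld = holosim.transmit(_simple_maps(), 12.7)
    out = holosim.propagate(fld, 0.05)
    assert out.intensity().sum() == pytest.approx(fld.intensity().sum(),
                                                  rel=1e-9)


def test_propagate_composes():
    fld = holosim.transmit(_simple_maps(), 12.7)
    one_step = holosim.propagate(fld, 0.06)
    two_step = holosim.propagate(holosim.propagate(fld, 0.02), 0.04)
    assert np.allclose(one_step.data, two_step.data, atol=1e-10)


def test_propagate_back_and_forth_is_identity():
    fld = holosim.transmit(_simple_maps(), 12.7)
    back = holosim.propagate(holosim.propagate(fld, 0.05), -0.05)
    assert np.allclose(back.data, fld.data, atol=1e-10)


def test_propagate_aliasing_guard():
    fld = holosim.transmit(_simple_maps(n=64), 12.7)
    with pytest.raises(holosim.AliasingError):
        holosim.propagate(fld, 10.0)


def test_propagate_1d():
    data = np.exp(1j * np.linspace(0, 1, 256))
    fld = holosim.ComplexField(data, 1e-6, 1e-10)
    out = holosim.propagate(fld, 0.05)
    assert out.data.shape == (256,)
    assert out.intensity().sum() == pytest.approx(fld.intensity().sum(),
                                                  rel=1e-9)


def test_partial_coherence_preserves_mean_and_smooths():
    rng = np.random.default_rng(0)
    inten = 1.0 + 0.1 * rng.standard_normal((128, 128))
    source = optics.SourceModel(fwhm_v=35e-6, fwhm_h=300e-6, distance=61.0)
    blurred = holosim.apply_partial_coherence(inten, source, z=5.0,
                                              pitch=0.6e-6)
    assert blurred.mean() == pytest.approx(inten.mean(), rel=1e-12)
    assert blurred.std() < inten.std()


def test_record_expectation_and_poisson():
    inten = np.full((16, 16), 2.0)
    expected = holosim.record(inten, None, 1e13, 0.017, 12.7, 0.6e-6,
                              seed=None)
    # 0.6 um pixel at 1e13 ph/s/mm^2 for 17 ms -> ~61 counts at intensity 1
    assert expected.data[0, 0] == pytest.approx(
        2.0 * 1e13 * (0.6e-3) ** 2 * 0.017, rel=1e-12)
    a = holosim.record(inten, None, 1e13, 0.017, 12.7, 0.6e-6, seed=42)
    b = holosim.record(inten, None, 1e13, 0.017, 12.7, 0.6e-6, seed=42)
    assert np.array_equal(a.data, b.data)          # seeded determinism
    assert np.all(a.data == np.rint(a.data))       # integer counts
    c = holosim.record(inten, None, 1e13, 0.017, 12.7, 0.6e-6, seed=43)
    assert not np.array_equal(a.data, c.data)


def test_record_flat_scales_expectation():
    inten = np.ones((8, 8))
    flat = np.full((8, 8), 0.5)
    out = holosim.record(inten, flat, 1e13, 0.017, 12.7, 0.6e-6, seed=None)
    ref = holosim.record(inten, None, 1e13, 0.017, 12.7, 0.6e-6, seed=None)
    assert np.allclose(out.data, 0.5 * ref.data)


def test_cone_to_parallel():
    z_eff, mag = holosim.cone_to_parallel(5.0, 61.0)
    assert z_eff == pytest.approx(5.0 * 61.0 / 66.0)
    assert mag == pytest.approx(66.0 / 61.0)
    z0, m0 = holosim.cone_to_parallel(0.0, 61.0)
    assert z0 == 0.0 and m0 == 1.0


def test_simulate_tomo_series_shapes_and_determinism():
    phant = make_crystal_mount_phantom(
        n_crystals=2, size_range=(24e-6, 40e-6), voxel=4e-6, grid=48,
        min_gap=25e-6, seed=1)
    gains = make_flat_fields(n=3, field_px=(48, 48), seed=2)
    source = optics.SourceModel(fwhm_v=35e-6, fwhm_h=300e-6, distance=61.0)
    stack, flats = holosim.simulate_tomo_series(
        phant, z=0.11, energy_kev=12.7, n_angles=12, step_deg=15.0,
        source=source, flats=gains, seed=7)
    assert stack.frames.shape == (12, 48, 48)
    assert len(flats) == 3
    assert len(stack.meta["flat_indices"]) == 12
    stack2, flats2 = holosim.simulate_tomo_series(
        phant, z=0.11, energy_kev=12.7, n_angles=12, step_deg=15.0,
        source=source, flats=gains, seed=7)
    assert np.array_equal(stack.frames, stack2.frames)
    assert all(np.array_equal(a, b) for a, b in zip(flats, flats2))


def test_projection_stack_validation():
    frames = np.zeros((4, 8, 8))
    with pytest.raises(ValueError):
        holosim.ProjectionStack(frames, np.array([0, 1, 2, 4.0]), 1e-6,
                                0.1, 12.7)
    with pytest.raises(ValueError):
        holosim.ProjectionStack(frames, np.array([0, 1.0]), 1e-6, 0.1, 12.7)
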