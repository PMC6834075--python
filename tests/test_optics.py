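"""Unit and property tests for the optics module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holotomo import optics


def test_wavelength_known_value():
    # lambda[A] = 12.398/E[keV]
    lam = optics.wavelength_from_energy(12.398)
    assert lam == pytest.approx(1e-10, rel=1e-4)
    with pytest.raises(ValueError):
        optics.wavelength_from_energy(0.0)


def test_beam_consistency_check():
    beam = optics.Beam.from_energy(12.7)
    assert beam.wavelength == pytest.approx(0.9763e-10, rel=1e-3)
    with pytest.raises(ValueError):
        optics.Beam(12.7, 2e-10)


@settings(max_examples=50, deadline=None)
@given(energy=st.floats(5.0, 30.0), distance=st.floats(1.0, 200.0),
       fwhm=st.floats(1e-6, 1e-3))
def test_coherence_max_source_inverse(energy, distance, fwhm):
    """max_source_size inverts coherence_length at the factor-15 criterion."""
    beam = optics.Beam.from_energy(energy)
    l_c = optics.coherence_length(beam, distance, fwhm)
    back = optics.max_source_size(l_c / 15.0, beam, distance)
    assert back == pytest.approx(fwhm, rel=1e-9)


def test_coherence_scalings():
    beam = optics.Beam.from_energy(12.0)
    base = optics.coherence_length(beam, 60.0, 20e-6)
    assert optics.coherence_length(beam, 120.0, 20e-6) == pytest.approx(2 * base)
    assert optics.coherence_length(beam, 60.0, 40e-6) == pytest.approx(base / 2)


@settings(max_examples=50, deadline=None)
@given(fwhm=st.floats(1e-6, 1e-4), spread=st.floats(0.0, 1e-5),
       dist=st.floats(0.0, 100.0))
def test_effective_source_quadrature_bounds(fwhm, spread, dist):
    d_eff = optics.effective_source_size(fwhm, spread, dist)
    assert d_eff >= max(fwhm, spread * dist) - 1e-30
    assert d_eff <= fwhm + spread * dist + 1e-30


def test_effective_source_printed_value():
    # 13 um vertical source + 0.7 urad over 45 m -> ~34 um (measured 35 +/- 3)
    d_eff = optics.effective_source_size(13e-6, 0.7e-6, 45.0)
    assert d_eff * 1e6 == pytest.approx(34.1, abs=0.2)
    assert abs(d_eff * 1e6 - 35.0) <= 3.0


def test_source_model_effective_fwhm():
    src = optics.SourceModel(fwhm_v=13e-6, fwhm_h=300e-6, distance=61.0,
                             dcm_distance=45.0, dcm_spread=0.7e-6)
    v, h = src.effective_fwhm()
    assert v == pytest.approx(np.hypot(13e-6, 0.7e-6 * 45.0))
    assert h > 300e-6


def test_optical_constants_identity():
    """beta and mu satisfy mu = 4 pi beta / lambda by construction."""
    for material in ("water", "beryllium", "protein"):
        for energy in (8.0, 12.7, 20.0):
            oc = optics.optical_constants(material, energy)
            lam = optics.wavelength_from_energy(energy)
            assert oc.mu == pytest.approx(4 * np.pi * oc.beta / lam, rel=1e-12)
            assert 0 < oc.beta < oc.delta  # far from edges for these materials


@settings(max_examples=30, deadline=None)
@given(energy=st.floats(5.0, 30.0))
def test_crl_focal_scales_with_energy_squared(energy):
    """F = R/(2 N delta) with delta ~ lambda^2 ~ 1/E^2, so F ~ E^2."""
    stack_e = optics.CRLStack(10, 50e-6, "beryllium", energy)
    stack_2e = optics.CRLStack(10, 50e-6, "beryllium", 10.0)
    f_e = optics.crl_focal_length(stack_e)
    f_10 = optics.crl_focal_length(stack_2e)
    assert f_e / f_10 == pytest.approx((energy / 10.0) ** 2, rel=1e-9)


def test_thin_lens_round_trip():
    focal = optics.thin_lens_solve(l1=0.4, l2=4.56)
    l2 = optics.thin_lens_solve(focal_length=focal, l1=0.4)
    assert l2 == pytest.approx(4.56, rel=1e-12)
    l1 = optics.thin_lens_solve(focal_length=focal, l2=4.56)
    assert l1 == pytest.approx(0.4, rel=1e-12)


def test_thin_lens_errors():
    with pytest.raises(optics.NoRealImageError):
        optics.thin_lens_solve(focal_length=0.5, l1=0.4)
    with pytest.raises(ValueError):
        optics.thin_lens_solve(l1=0.4)
    with pytest.raises(ValueError):
        optics.thin_lens_solve(focal_length=0.5, l1=-1.0)


def test_imaging_geometry_validation():
    with pytest.raises(ValueError):
        optics.ImagingGeometry(l1=0.4, l2=4.56, detector_pixel=0.6e-6,
                               focal_length=0.2)
    geom = optics.ImagingGeometry(l1=0.4, l2=4.56, detector_pixel=0.6e-6)
    assert geom.l1 == 0.4


def test_crl_resolution_order_100nm():
    """The CRL microscope configuration resolves at the ~100 nm scale."""
    stack = optics.CRLStack(20, 50e-6, "beryllium", 10.0)
    a_eff, res = optics.crl_resolution(stack, l1=0.40)
    assert 50e-9 < res < 300e-9
    assert 100e-6 < a_eff < 500e-6
    # halving the aperture doubles the diffraction limit
    _, res_half = optics.crl_resolution(stack, l1=0.40,
                                        aperture_correction=0.5)
    assert res_half == pytest.approx(2 * res, rel=1e-12)


def test_unknown_material_raises():
    with pytest.raises(optics.MaterialLookupError):
        optics.optical_constants("unobtainium", 12.0)
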