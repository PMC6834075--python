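"""Unit tests for materials tables and the dose model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holotomo import dose, materials


# -- materials ---------------------------------------------------------------

def test_grid_point_values_match_tables():
    # mu/rho of water at 10 keV: 5.3287 cm^2/g (NIST-style table entry)
    assert materials.mass_attenuation("water", 10.0) == pytest.approx(
        0.53287, rel=1e-6)
    assert materials.mass_energy_absorption("water", 15.0) == pytest.approx(
        0.13678, rel=1e-6)


def test_loglog_interpolation_monotone_and_bracketed():
    lo = materials.mass_attenuation("water", 12.0)
    mid = materials.mass_attenuation("water", 13.5)
    hi = materials.mass_attenuation("water", 15.0)
    assert hi < mid < lo  # photoelectric cross sections fall with energy


def test_aliases_and_case():
    assert materials.canonical_name("LCP") == "lipid"
    assert materials.canonical_name("Be") == "beryllium"
    assert materials.canonical_name(" WATER ") == "water"


def test_unknown_material_and_energy_raise():
    with pytest.raises(materials.MaterialLookupError):
        materials.canonical_name("adamantium")
    with pytest.raises(materials.MaterialLookupError):
        materials.mass_attenuation("water", 2.0)
    with pytest.raises(materials.MaterialLookupError):
        materials.mass_energy_absorption("water", 100.0)


def test_electron_density_water():
    # ~3.34e29 electrons / m^3 for liquid water
    assert materials.electron_density("water") == pytest.approx(
        3.343e29, rel=1e-3)


# -- dose --------------------------------------------------------------------

def test_dose_known_value_single_projection():
    spec = dose.ExposureSpec(exposure_time=0.017, energy_kev=12.7,
                             flux_density=1e13)
    result = dose.dose_from_exposure(spec, "water")
    assert result.dose_gy == pytest.approx(81.2, rel=0.01)
    assert result.fluence == pytest.approx(1e13 * 1e6 * 0.017, rel=1e-12)


@settings(max_examples=40, deadline=None)
@given(t=st.floats(1e-4, 10.0), phi=st.floats(1e9, 1e15),
       k=st.floats(0.1, 10.0))
def test_dose_linear_in_time_and_flux(t, phi, k):
    base = dose.dose_from_exposure(
        dose.ExposureSpec(exposure_time=t, energy_kev=12.7,
                          flux_density=phi), "water").dose_gy
    scaled_t = dose.dose_from_exposure(
        dose.ExposureSpec(exposure_time=k * t, energy_kev=12.7,
                          flux_density=phi), "water").dose_gy
    scaled_phi = dose.dose_from_exposure(
        dose.ExposureSpec(exposure_time=t, energy_kev=12.7,
                          flux_density=k * phi), "water").dose_gy
    assert scaled_t == pytest.approx(k * base, rel=1e-9)
    assert scaled_phi == pytest.approx(k * base, rel=1e-9)


def test_flux_area_consistency_check():
    with pytest.raises(ValueError):
        dose.ExposureSpec(exposure_time=1.0, energy_kev=12.7,
                          flux_density=1e13, flux=1e12, area_mm2=1.0)
    spec = dose.ExposureSpec(exposure_time=1.0, energy_kev=12.7,
                             flux=4e12, area_mm2=0.614 * 0.614)
    assert spec.flux_density_mm2 == pytest.approx(1.061e13, rel=1e-3)


def test_missing_flux_information_raises():
    with pytest.raises(ValueError):
        dose.ExposureSpec(exposure_time=1.0, energy_kev=12.7)
    with pytest.raises(ValueError):
        dose.ExposureSpec(exposure_time=1.0, energy_kev=12.7, flux=1e12)


def test_dwell_time_scanned_beam():
    """For raster scans the per-spot dwell time sets the dose, not the
    total scan duration."""
    scan = dose.ExposureSpec(exposure_time=37.5, dwell_time=0.0075,
                             energy_kev=12.7, flux=1.2e13,
                             area_mm2=0.005 * 0.010)
    static = dose.ExposureSpec(exposure_time=0.0075, energy_kev=12.7,
                               flux=1.2e13, area_mm2=0.005 * 0.010)
    d_scan = dose.dose_from_exposure(scan, "water").dose_gy
    d_static = dose.dose_from_exposure(static, "water").dose_gy
    assert d_scan == pytest.approx(d_static, rel=1e-12)
    assert scan.total_exposure_time == 37.5


def test_table1_report_structure():
    frame = dose.table1_report()
    assert list(frame["scenario"]) == [
        "raster scan", "imaging (single shot)",
        "tomography (180 projections)", "microscopy (single shot)"]
    imaging = frame[frame["scenario"] == "imaging (single shot)"].iloc[0]
    assert imaging["dose_kgy"] * 1e3 == pytest.approx(86.2, rel=0.01)
    tomo = frame[frame["scenario"] == "tomography (180 projections)"].iloc[0]
    assert tomo["total_exposure_s"] == pytest.approx(3.06, rel=1e-9)
    micro = frame[frame["scenario"] == "microscopy (single shot)"].iloc[0]
    assert micro["flux_density_ph_s_mm2"] == pytest.approx(5.14e14, rel=0.01)
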