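"""Thin-sample absorbed-dose accounting.

For a sample much thinner than the attenuation length, the absorbed dose is
the collision kerma of the incident fluence,

    D = Phi_A * t * E_photon * (mu_en / rho),

with Phi_A the photon flux density, t the exposure time, E_photon the photon
energy and mu_en/rho the mass energy-absorption coefficient of the absorber.
No depth attenuation or photoelectron escape is modelled, which is adequate
for the <= 100 um aqueous samples this toolkit targets at >= 10 keV.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import constants as const

from . import materials

__all__ = ["ExposureSpec", "DoseResult", "dose_from_exposure", "table1_report"]


@dataclass(frozen=True)
class ExposureSpec:
    """One irradiation scenario.

    ``flux_density`` is in photons s^-1 mm^-2.  Alternatively give the total
    ``flux`` (photons s^-1) plus the illuminated ``area_mm2``; if both routes
    are given they must agree to 0.1%.
    """

    exposure_time: float                 # s (per repeat)
    energy_kev: float
    flux_density: float | None = None    # photons s^-1 mm^-2
    flux: float | None = None            # photons s^-1
    area_mm2: float | None = None
    n_repeats: int = 1
    dwell_time: float | None = None      # s a single spot is illuminated, for
                                         # scanned beams (defaults to exposure_time)
    name: str = ""

    def __post_init__(self):
        if self.exposure_time < 0 or self.energy_kev <= 0 or self.n_repeats < 0:
            raise ValueError("exposure parameters must be non-negative")
        if self.flux_density is None and (self.flux is None or self.area_mm2 is None):
            raise ValueError("give flux_density, or flux together with area_mm2")
        if (self.flux_density is not None and self.flux is not None
                and self.area_mm2 is not None):
            derived = self.flux / self.area_mm2
            if abs(derived - self.flux_density) > 1e-3 * derived:
                raise ValueError(
                    f"flux/area = {derived:g} disagrees with flux_density = "
                    f"{self.flux_density:g} photons s^-1 mm^-2"
                )

    @property
    def flux_density_mm2(self) -> float:
        if self.flux_density is not None:
            return self.flux_density
        return self.flux / self.area_mm2

    @property
    def total_exposure_time(self) -> float:
        return self.exposure_time * self.n_repeats

    @property
    def dose_time(self) -> float:
        """Time a fixed sample spot is illuminated, summed over repeats."""
        per_repeat = self.exposure_time if self.dwell_time is None else self.dwell_time
        return per_repeat * self.n_repeats


@dataclass(frozen=True)
class DoseResult:
    dose_gy: float
    fluence: float          # photons m^-2
    energy_fluence: float   # J m^-2
    absorber: str


def dose_from_exposure(spec: ExposureSpec, absorber: str = "water") -> DoseResult:
    """Thin-sample kerma dose for an exposure scenario."""
    key = materials.canonical_name(absorber)
    fluence = spec.flux_density_mm2 * 1e6 * spec.dose_time  # m^-2
    e_photon = spec.energy_kev * 1e3 * const.e                        # J
    energy_fluence = fluence * e_photon
    mu_en_rho = materials.mass_energy_absorption(key, spec.energy_kev)
    return DoseResult(energy_fluence * mu_en_rho, fluence, energy_fluence, key)


def default_scenarios() -> list[ExposureSpec]:
    """The four canonical beamline scenarios: diffraction raster scan,
    single-shot projection imaging, 180-projection tomography and
    CRL-magnified microscopy."""
    return [
        ExposureSpec(name="raster scan", flux=1.2e13, area_mm2=0.005 * 0.010,
                     exposure_time=37.5, dwell_time=0.0075, energy_kev=12.7),
        ExposureSpec(name="imaging (single shot)", flux=4e12,
                     area_mm2=0.614 * 0.614, exposure_time=0.017,
                     energy_kev=12.7),
        ExposureSpec(name="tomography (180 projections)", flux=4e12,
                     area_mm2=0.614 * 0.614, exposure_time=0.017,
                     n_repeats=180, energy_kev=12.7),
        ExposureSpec(name="microscopy (single shot)", flux=1.5e12,
                     area_mm2=0.054 * 0.054, exposure_time=1.0,
                     energy_kev=10.0),
    ]


def table1_report(specs: list[ExposureSpec] | None = None,
                  absorber: str = "water") -> pd.DataFrame:
    """Flux-density / exposure / dose summary for a list of scenarios.

    With no argument, reports the four default beamline scenarios.  Doses
    for the focused-beam scenarios (raster scan, microscopy) depend strongly
    on the absorber composition assumed; the default is water.
    """
    if specs is None:
        specs = default_scenarios()
    rows = []
    for spec in specs:
        result = dose_from_exposure(spec, absorber)
        rows.append({
            "scenario": spec.name,
            "flux_density_ph_s_mm2": spec.flux_density_mm2,
            "total_exposure_s": spec.total_exposure_time,
            "energy_kev": spec.energy_kev,
            "dose_kgy": result.dose_gy / 1e3,
        })
    return pd.DataFrame(rows)
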