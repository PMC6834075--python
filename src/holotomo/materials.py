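"""X-ray optical constants for the materials the toolkit supports.

Mass attenuation coefficients (mu/rho) and mass energy-absorption
coefficients (mu_en/rho) are embedded as small tables on a 5-30 keV grid,
taken from the standard NIST compilations (XCOM photon cross sections and
the Hubbell & Seltzer mass energy-absorption tables); values between grid
points are obtained by log-log interpolation, the conventional practice for
smooth photoelectric cross sections away from absorption edges.

The refractive-index decrement delta is computed analytically from the
electron density, delta = r_e * lambda**2 * n_e / (2*pi), which is accurate
far from absorption edges; beta is derived from mu so that the identity
mu = 4*pi*beta/lambda holds exactly.

Densities are bulk values (g/cm^3).  "protein" uses an average crystal
composition H50 C30 N9 O10 S; "lipid" is monoolein (C21 H40 O4), the host
lipid of a lipidic cubic phase; "kapton" is the polyimide C22 H10 N2 O5.
"""

from __future__ import annotations

import numpy as np

#: Tabulation energies (keV).
ENERGY_GRID_KEV = np.array([5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0, 25.0, 30.0])

# name -> (density g/cm^3, Z/A electrons per atomic mass unit,
#          mu/rho table cm^2/g, mu_en/rho table cm^2/g)
_TABLES = {
    "beryllium": (
        1.85, 0.44384,
        [4.369, 2.5275, 1.1238, 0.6466, 0.4418, 0.3070, 0.2251, 0.1944, 0.1792],
        [1.7704, 0.6604, 0.2305, 0.1517, 0.1097, 0.0733, 0.0389, 0.0251, 0.0178],
    ),
    "boron": (
        2.34, 0.46249,
        [9.682, 5.5392, 2.3465, 1.2549, 0.7877, 0.4827, 0.3014, 0.2364, 0.2064],
        [9.3277, 4.9733, 1.0402, 0.3634, 0.2255, 0.1257, 0.0717, 0.0445, 0.0306],
    ),
    "tungsten": (
        19.3, 0.40252,
        [553.22, 351.31, 170.52, 96.900, 210.67, 138.89, 65.721, 36.579, 22.732],
        [541.63, 342.31, 163.95, 91.842, 171.04, 116.55, 56.922, 32.077, 19.871],
    ),
    "tantalum": (
        16.65, 0.40343,
        [532.92, 338.22, 163.90, 237.89, 235.23, 134.02, 63.343, 35.225, 21.876],
        [521.82, 329.57, 157.69, 202.11, 194.04, 113.88, 55.306, 31.058, 19.195],
    ),
    "water": (
        1.00, 0.55509,
        [42.582, 24.636, 10.371, 5.3287, 3.1258, 1.6722, 0.8097, 0.5082, 0.3756],
        [41.845, 24.029, 9.9011, 4.9358, 2.8213, 1.3678, 0.3823, 0.1802, 0.0981],
    ),
    "protein": (
        1.35, 0.53372,
        [40.773, 23.956, 10.314, 5.3829, 3.1925, 1.7240, 0.8361, 0.5205, 0.3803],
        [39.677, 23.182, 9.8136, 4.7354, 2.5744, 1.2212, 0.4617, 0.2408, 0.1425],
    ),
    "lipid": (
        0.94, 0.55537,
        [22.164, 12.758, 5.3681, 2.7903, 1.6749, 0.9432, 0.5097, 0.3574, 0.2895],
        [21.649, 12.306, 5.0003, 2.1027, 1.0587, 0.4537, 0.1630, 0.0910, 0.0579],
    ),
    "kapton": (
        1.42, 0.51264,
        [25.549, 14.695, 6.1602, 3.1799, 1.8894, 1.0427, 0.5415, 0.3660, 0.2880],
        [25.008, 14.227, 5.7874, 2.5015, 1.2615, 0.5423, 0.1875, 0.1030, 0.0642],
    ),
}

#: Alias accepted for the lipidic-cubic-phase matrix.
_ALIASES = {"lcp": "lipid", "be": "beryllium", "b": "boron", "w": "tungsten",
            "ta": "tantalum", "h2o": "water"}

SUPPORTED_MATERIALS = tuple(sorted(_TABLES))


class MaterialLookupError(KeyError):
    """Unknown material or energy outside the tabulated span."""


def canonical_name(material: str) -> str:
    key = material.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _TABLES:
        raise MaterialLookupError(
            f"unknown material {material!r}; supported: {', '.join(SUPPORTED_MATERIALS)}"
        )
    return key


def density(material: str) -> float:
    """Bulk density in g/cm^3."""
    return _TABLES[canonical_name(material)][0]


def electron_density(material: str) -> float:
    """Electron number density in m^-3."""
    rho, z_over_a, _, _ = _TABLES[canonical_name(material)]
    avogadro = 6.02214076e23
    return rho * z_over_a * avogadro * 1e6  # g/cm^3 -> m^-3


def _loglog_interp(energy_kev: float, table: list[float], material: str) -> float:
    grid = ENERGY_GRID_KEV
    if not (grid[0] <= energy_kev <= grid[-1]):
        raise MaterialLookupError(
            f"energy {energy_kev} keV outside tabulated span "
            f"[{grid[0]}, {grid[-1]}] keV for {material!r}"
        )
    return float(np.exp(np.interp(np.log(energy_kev), np.log(grid), np.log(table))))


def mass_attenuation(material: str, energy_kev: float) -> float:
    """Mass attenuation coefficient mu/rho in m^2/kg."""
    key = canonical_name(material)
    cm2_per_g = _loglog_interp(energy_kev, _TABLES[key][2], key)
    return cm2_per_g * 0.1  # cm^2/g -> m^2/kg


def mass_energy_absorption(material: str, energy_kev: float) -> float:
    """Mass energy-absorption coefficient mu_en/rho in m^2/kg."""
    key = canonical_name(material)
    cm2_per_g = _loglog_interp(energy_kev, _TABLES[key][3], key)
    return cm2_per_g * 0.1
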